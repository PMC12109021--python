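"""Quantification of spheroid-laden hydrogel patch images.

A degrading fibrin patch imaged in brightfield shows three intensity
populations: dark background (and holes torn in the matrix), mid-intensity
hydrogel, and bright multicellular spheroids.  Two metrics summarize a
patch:

* **percent degraded** — 100 × (summed hole area) / (total matrix area),
  where holes are dark connected regions strictly inside the matrix;
* **inter-spheroid nearest-neighbor distance** — for every spheroid, the
  Euclidean center-to-center distance to its closest neighbor.

Manual outlining in an image editor is replaced here by a reproducible
surrogate: global thresholding (Otsu / 3-class multi-Otsu by default),
8-connected component labeling, and minimum-area filters.  All outputs are
in physical units via the required μm/pixel metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters, measure

from .errors import InsufficientObjectsError, InvalidInputError

#: Default minimum spheroid area: a 100 μm-diameter disc.
MIN_SPHEROID_AREA_UM2 = math.pi * 50.0**2
#: Default minimum hole area: a 50 μm-diameter disc.
MIN_HOLE_AREA_UM2 = math.pi * 25.0**2

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class PatchImage:
    """Single-channel patch micrograph with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    timestamp_label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or min(px.shape) < 64:
            raise InvalidInputError("image must be 2D and at least 64x64")
        if not self.pixel_size_um > 0:
            raise InvalidInputError("pixel size must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class RegionSet:
    """Labeled regions with physical-unit areas and centroids.

    ``centroids_um`` is an (n, 2) array of (x, y) positions, x along image
    columns and y along rows, both in μm.
    """

    labels: np.ndarray
    areas_um2: np.ndarray
    centroids_um: np.ndarray
    pixel_size_um: float

    @property
    def n_regions(self) -> int:
        return len(self.areas_um2)


@dataclass(frozen=True)
class MatrixMask:
    mask: np.ndarray
    area_um2: float


@dataclass(frozen=True)
class PatchQuantResult:
    matrix_area_um2: float
    hole_areas_um2: list[float]
    percent_degraded: float
    spheroid_centroids_um: np.ndarray
    spheroid_areas_um2: np.ndarray
    nn_distances_um: np.ndarray | None
    nn_mean_um: float | None
    nn_sd_um: float | None

    def to_dict(self) -> dict:
        return {
            "matrix_area_um2": self.matrix_area_um2,
            "hole_areas_um2": list(map(float, self.hole_areas_um2)),
            "percent_degraded": self.percent_degraded,
            "n_spheroids": int(len(self.spheroid_areas_um2)),
            "spheroid_centroids_um": self.spheroid_centroids_um.tolist(),
            "spheroid_areas_um2": self.spheroid_areas_um2.tolist(),
            "nn_distances_um": (
                None
                if self.nn_distances_um is None
                else self.nn_distances_um.tolist()
            ),
            "nn_mean_um": self.nn_mean_um,
            "nn_sd_um": self.nn_sd_um,
        }


def auto_thresholds(image: PatchImage) -> tuple[float, float]:
    """(low, high) intensity cuts separating background/holes, matrix, spheroids.

    3-class multi-Otsu when the histogram supports it.  Degenerate images
    (fewer than three distinct values) fall back to cuts that classify
    everything as matrix: nothing darker, nothing brighter.
    """
    px = image.pixels
    if len(np.unique(px)) < 3:
        lo = float(px.min()) - 1.0
        hi = float(px.max()) + 1.0
        return lo, hi
    lo, hi = filters.threshold_multiotsu(px, classes=3)
    return float(lo), float(hi)


def _regions_from_mask(
    mask: np.ndarray, pixel_size_um: float, min_area_um2: float
) -> RegionSet:
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    props = measure.regionprops(labels)
    px_area = pixel_size_um**2
    keep, areas, cents = [], [], []
    for p in props:
        area = p.area * px_area
        if area >= min_area_um2:
            keep.append(p.label)
            areas.append(area)
            row, col = p.centroid
            cents.append((col * pixel_size_um, row * pixel_size_um))
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return RegionSet(
        labels=out,
        areas_um2=np.asarray(areas, dtype=float),
        centroids_um=(
            np.asarray(cents, dtype=float) if cents else np.empty((0, 2))
        ),
        pixel_size_um=pixel_size_um,
    )


def segment_spheroids(
    image: PatchImage,
    threshold: float | None = None,
    min_area_um2: float | None = None,
) -> RegionSet:
    """Detect bright spheroid regions by global threshold + labeling.

    Default threshold is Otsu's; pass an explicit value (e.g. the high cut
    of :func:`auto_thresholds`) when the image also contains a mid-intensity
    matrix that Otsu would lump in with the spheroids.  Regions smaller
    than a 100 μm-diameter disc are discarded.  An image with no regions
    yields an empty :class:`RegionSet`, not an error.
    """
    if min_area_um2 is None:
        min_area_um2 = MIN_SPHEROID_AREA_UM2
    px = image.pixels
    if threshold is None:
        if len(np.unique(px)) < 2:
            return _regions_from_mask(
                np.zeros(px.shape, dtype=bool), image.pixel_size_um, min_area_um2
            )
        threshold = float(filters.threshold_otsu(px))
    return _regions_from_mask(px > threshold, image.pixel_size_um, min_area_um2)


def matrix_mask(
    image: PatchImage, low_threshold: float | None = None
) -> MatrixMask:
    """Largest connected bright/mid-intensity region, holes filled.

    The matrix is everything above the low cut — hydrogel plus embedded
    spheroids — taken as the largest 8-connected component with interior
    dark regions (candidate holes) filled in, so the reported matrix area
    is the area the gel originally covered.
    """
    if low_threshold is None:
        low_threshold = auto_thresholds(image)[0]
    bright = image.pixels > low_threshold
    labels, n = ndimage.label(bright, structure=_EIGHT)
    if n == 0:
        return MatrixMask(mask=np.zeros_like(bright), area_um2=0.0)
    sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    area = float(mask.sum()) * image.pixel_size_um**2
    return MatrixMask(mask=mask, area_um2=area)


def detect_holes(
    image: PatchImage,
    matrix: MatrixMask,
    low_threshold: float | None = None,
    min_area_um2: float | None = None,
    exclude: RegionSet | None = None,
) -> RegionSet:
    """Dark connected regions strictly inside the matrix mask.

    Regions touching the matrix border (8-adjacent to any pixel outside
    the mask) are edge indentations, not holes, and are excluded; so are
    pixels of ``exclude`` regions (e.g. segmented spheroids) and regions
    smaller than a 50 μm-diameter disc.
    """
    if low_threshold is None:
        low_threshold = auto_thresholds(image)[0]
    if min_area_um2 is None:
        min_area_um2 = MIN_HOLE_AREA_UM2
    dark = (image.pixels <= low_threshold) & matrix.mask
    if exclude is not None:
        dark &= exclude.labels == 0
    outside = ~matrix.mask
    near_border = ndimage.binary_dilation(outside, structure=_EIGHT)
    labels, n = ndimage.label(dark, structure=_EIGHT)
    drop = set()
    if n:
        touching = np.unique(labels[near_border & (labels > 0)])
        drop = set(int(t) for t in touching)
    interior = dark & ~np.isin(labels, sorted(drop))
    return _regions_from_mask(interior, image.pixel_size_um, min_area_um2)


def percent_degraded(holes: RegionSet, matrix_area_um2: float) -> float:
    """100 × Σ hole areas / matrix area."""
    if not matrix_area_um2 > 0:
        raise InvalidInputError("matrix area must be positive")
    return 100.0 * float(holes.areas_um2.sum()) / matrix_area_um2


@dataclass(frozen=True)
class NNResult:
    distances_um: np.ndarray
    mean_um: float
    sd_um: float


def nn_distances(spheroids: RegionSet | np.ndarray) -> NNResult:
    """Nearest-neighbor center-to-center distance for every spheroid.

    Accepts a :class:`RegionSet` or an (n, 2) array of centroid positions
    in μm.  Requires at least two spheroids.
    """
    pts = (
        spheroids.centroids_um
        if isinstance(spheroids, RegionSet)
        else np.asarray(spheroids, dtype=float)
    )
    if len(pts) < 2:
        raise InsufficientObjectsError(
            "nearest-neighbor distances need at least two spheroids"
        )
    dist, _ = cKDTree(pts).query(pts, k=2)
    d = dist[:, 1]
    return NNResult(
        distances_um=d, mean_um=float(d.mean()), sd_um=float(d.std(ddof=1))
    )


def quantify_patch(
    image: PatchImage,
    thresholds: tuple[float, float] | None = None,
    spheroid_min_area_um2: float | None = None,
    hole_min_area_um2: float | None = None,
) -> PatchQuantResult:
    """End-to-end quantification of one patch image.

    Thresholds default to the 3-class multi-Otsu cuts; spheroids use the
    high cut, matrix and holes the low cut.
    """
    lo, hi = thresholds if thresholds is not None else auto_thresholds(image)
    spheroids = segment_spheroids(
        image, threshold=hi, min_area_um2=spheroid_min_area_um2
    )
    matrix = matrix_mask(image, low_threshold=lo)
    holes = detect_holes(
        image,
        matrix,
        low_threshold=lo,
        min_area_um2=hole_min_area_um2,
        exclude=spheroids,
    )
    pct = (
        percent_degraded(holes, matrix.area_um2) if matrix.area_um2 > 0 else 0.0
    )
    if spheroids.n_regions >= 2:
        nn = nn_distances(spheroids)
        nn_d, nn_mean, nn_sd = nn.distances_um, nn.mean_um, nn.sd_um
    else:
        nn_d = nn_mean = nn_sd = None
    return PatchQuantResult(
        matrix_area_um2=matrix.area_um2,
        hole_areas_um2=list(map(float, holes.areas_um2)),
        percent_degraded=pct,
        spheroid_centroids_um=spheroids.centroids_um,
        spheroid_areas_um2=spheroids.areas_um2,
        nn_distances_um=nn_d,
        nn_mean_um=nn_mean,
        nn_sd_um=nn_sd,
    )
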