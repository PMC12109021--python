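"""Structured run configuration.

One YAML file configures a whole characterization run.  Keys carry unit
suffixes (``Ly_m``, ``density_kg_m3``, ``pixel_size_um``) so a value can
never be silently read in the wrong unit; unknown keys are rejected rather
than ignored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .duct import SeriesConfig
from .errors import ConfigError
from .flow import ChannelGeometry, FluidProperties


@dataclass(frozen=True)
class GatingConfig:
    control_label: str = "killed_control"
    quantile: float = 0.01

    def __post_init__(self):
        if not (0 < self.quantile <= 0.5):
            raise ConfigError("gating quantile must be in (0, 0.5]")


@dataclass(frozen=True)
class ImageConfig:
    pixel_size_um: float = 10.0
    spheroid_min_area_um2: float | None = None
    hole_min_area_um2: float | None = None

    def __post_init__(self):
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel size must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of all stage parameters."""

    fluid: FluidProperties = field(default_factory=FluidProperties)
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    series: SeriesConfig = field(default_factory=SeriesConfig)
    gating: GatingConfig = field(default_factory=GatingConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    velocity_ratio_mode: str = "table1"
    seed: int = 0

    def __post_init__(self):
        if self.velocity_ratio_mode not in ("table1", "rect-duct"):
            raise ConfigError(
                f"unknown velocity_ratio_mode {self.velocity_ratio_mode!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable content hash for provenance logging."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


_KEY_MAP = {
    "fluid": {
        "density_kg_m3": "density_kg_m3",
        "viscosity_Pa_s": "viscosity_Pa_s",
    },
    "geometry": {
        "Ly_m": "width_Ly_m",
        "Lz_m": "height_Lz_m",
        "Ac_m2": "cross_section_area_Ac_m2",
        "D_as_printed": "hydraulic_diameter_D",
    },
    "series": {
        "n_odd_terms_per_axis": "n_odd_terms_per_axis",
        "grid_points_per_axis": "grid_points_per_axis",
        "term_ordering": "term_ordering",
    },
    "gating": {"control_label": "control_label", "quantile": "quantile"},
    "image": {
        "pixel_size_um": "pixel_size_um",
        "spheroid_min_area_um2": "spheroid_min_area_um2",
        "hole_min_area_um2": "hole_min_area_um2",
    },
}
_SECTION_TYPES = {
    "fluid": FluidProperties,
    "geometry": ChannelGeometry,
    "series": SeriesConfig,
    "gating": GatingConfig,
    "image": ImageConfig,
}
_TOP_SCALARS = {"velocity_ratio_mode", "seed"}


def config_from_dict(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a nested mapping, rejecting unknowns."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _TOP_SCALARS:
            kwargs[key] = value
        elif key in _KEY_MAP:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            mapped = {}
            for k, v in value.items():
                if k not in _KEY_MAP[key]:
                    raise ConfigError(f"unknown config key {key}.{k}")
                mapped[_KEY_MAP[key][k]] = v
            try:
                kwargs[key] = _SECTION_TYPES[key](**mapped)
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"invalid {key} section: {exc}") from exc
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
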