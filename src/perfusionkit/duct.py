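"""Creeping-flow velocity profile in a rectangular duct.

For fully developed, steady, unidirectional laminar flow of a Newtonian
fluid the axial Navier–Stokes equation reduces to a Poisson problem over
the duct cross-section,

    μ (∂²u/∂y² + ∂²u/∂z²) = dp/dx,     u = 0 on the walls,

whose classical double-Fourier solution over 0 ≤ y ≤ Ly, 0 ≤ z ≤ Lz is

    u(y,z) = Σ_m Σ_n  16(−dp/dx) / (μ π⁴ m n (m²/Ly² + n²/Lz²))
                      · sin(mπy/Ly) · sin(nπz/Lz),   m, n odd.

Two solvers are provided: the truncated series (default: the first 15 odd
indices per axis, 225 products) and an independent finite-difference
Poisson solver on the same grid, used as a numerical oracle for the series
and as a desk-scale stand-in for a full CFD run.  Because the problem is
linear in dp/dx, the pressure gradient that produces a desired peak
velocity is obtained exactly by rescaling a unit-gradient solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigError, InvalidInputError, NumericalError
from .flow import ChannelGeometry, FluidProperties
from .units import M_PER_S_TO_UM_PER_S

#: Grid size (points per axis) above which the finite-difference solver
#: switches from a sparse direct factorization to conjugate gradients.
DIRECT_SOLVE_MAX_POINTS = 200

#: Required relative residual of the finite-difference linear solve.
FD_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation and sampling of the analytical series.

    ``term_ordering`` selects how "first N terms" is read for the double
    sum: ``"per-axis"`` takes the first N odd indices on each axis (N²
    products, the default); ``"radial"`` takes the N odd (m, n) pairs of
    smallest m² + n², for sensitivity analysis of the truncation rule.
    The grid is odd-sized so the geometric center is a node.
    """

    n_odd_terms_per_axis: int = 15
    grid_points_per_axis: int = 101
    term_ordering: str = "per-axis"

    def __post_init__(self):
        if self.n_odd_terms_per_axis < 1:
            raise ConfigError("need at least one series term")
        if self.grid_points_per_axis < 3:
            raise InvalidInputError("grid must have at least 3 points per axis")
        if self.grid_points_per_axis % 2 == 0:
            raise ConfigError(
                "grid_points_per_axis must be odd so the center is a node"
            )
        if self.term_ordering not in ("per-axis", "radial"):
            raise ConfigError(f"unknown term ordering {self.term_ordering!r}")


@dataclass(frozen=True)
class VelocityProfile:
    """Gridded axial velocity U(y,z) with its driving pressure gradient.

    ``u_um_per_s`` is indexed ``[i_y, i_z]`` on the node coordinates
    ``y_m``/``z_m`` (walls included; U = 0 there).  ``dpdx_Pa_per_m`` is the
    signed axial gradient: a negative gradient drives positive flow.
    """

    u_um_per_s: np.ndarray
    y_m: np.ndarray
    z_m: np.ndarray
    Ly_m: float
    Lz_m: float
    dpdx_Pa_per_m: float
    provenance: str

    @property
    def u_max_um_per_s(self) -> float:
        return float(self.u_um_per_s.max())


@dataclass(frozen=True)
class ProfileStats:
    u_max_um_per_s: float
    u_mean_um_per_s: float
    max_to_mean_ratio: float
    flow_rate_uL_per_s: float


def _grid(geometry: ChannelGeometry, n: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.linspace(0.0, geometry.width_Ly_m, n)
    z = np.linspace(0.0, geometry.height_Lz_m, n)
    return y, z


def _series_terms(cfg: SeriesConfig) -> list[tuple[int, int]]:
    if cfg.term_ordering == "per-axis":
        odds = [2 * k + 1 for k in range(cfg.n_odd_terms_per_axis)]
        return [(m, n) for m in odds for n in odds]
    # radial: the n_odd_terms_per_axis odd (m, n) pairs of smallest m²+n²
    count = cfg.n_odd_terms_per_axis
    span = 2 * count + 1
    odds = range(1, 2 * span, 2)
    pairs = sorted(
        ((m, n) for m in odds for n in odds),
        key=lambda mn: (mn[0] ** 2 + mn[1] ** 2, mn[0]),
    )
    return pairs[:count]


def series_profile(
    geometry: ChannelGeometry,
    dpdx_Pa_per_m: float,
    fluid: FluidProperties | None = None,
    cfg: SeriesConfig | None = None,
) -> VelocityProfile:
    """Evaluate the truncated double-sine series on the node grid."""
    fluid = fluid or FluidProperties()
    cfg = cfg or SeriesConfig()
    Ly, Lz = geometry.width_Ly_m, geometry.height_Lz_m
    y, z = _grid(geometry, cfg.grid_points_per_axis)
    Y, Z = np.meshgrid(y, z, indexing="ij")
    mu = fluid.viscosity_Pa_s
    pref = 16.0 * (-dpdx_Pa_per_m) / (mu * np.pi**4)
    u = np.zeros_like(Y)
    for m, n in _series_terms(cfg):
        coef = pref / (m * n * (m**2 / Ly**2 + n**2 / Lz**2))
        u += coef * np.sin(m * np.pi * Y / Ly) * np.sin(n * np.pi * Z / Lz)
    # the sine basis vanishes on the walls analytically; enforce it exactly
    u[0, :] = u[-1, :] = u[:, 0] = u[:, -1] = 0.0
    return VelocityProfile(
        u_um_per_s=u * M_PER_S_TO_UM_PER_S,
        y_m=y,
        z_m=z,
        Ly_m=Ly,
        Lz_m=Lz,
        dpdx_Pa_per_m=dpdx_Pa_per_m,
        provenance="series",
    )


def fd_poisson_profile(
    geometry: ChannelGeometry,
    dpdx_Pa_per_m: float,
    fluid: FluidProperties | None = None,
    grid_points: int = 129,
) -> VelocityProfile:
    """Finite-difference oracle: 5-point Laplacian with zero wall values.

    Solves −∇²u = (−dp/dx)/μ by a sparse direct factorization below
    :data:`DIRECT_SOLVE_MAX_POINTS` points per axis and by conjugate
    gradients above, verifying the residual against
    :data:`FD_RESIDUAL_TOL` · ‖b‖ in both cases.
    """
    fluid = fluid or FluidProperties()
    if grid_points < 17:
        raise InvalidInputError("finite-difference grid needs >= 17 points")
    Ly, Lz = geometry.width_Ly_m, geometry.height_Lz_m
    n = grid_points
    y, z = _grid(geometry, n)
    hy = Ly / (n - 1)
    hz = Lz / (n - 1)
    ni = n - 2
    ty = sp.diags([-1.0, 2.0, -1.0], [-1, 0, 1], shape=(ni, ni)) / hy**2
    tz = sp.diags([-1.0, 2.0, -1.0], [-1, 0, 1], shape=(ni, ni)) / hz**2
    A = (sp.kron(ty, sp.eye(ni)) + sp.kron(sp.eye(ni), tz)).tocsr()
    g = -dpdx_Pa_per_m / fluid.viscosity_Pa_s
    b = np.full(ni * ni, g)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        ui = np.zeros(ni * ni)
    elif n < DIRECT_SOLVE_MAX_POINTS:
        ui = spla.spsolve(A.tocsc(), b)
    else:
        ui, info = spla.cg(A, b, rtol=1e-12, atol=0.0, maxiter=50_000)
        if info != 0:
            res = float(np.linalg.norm(b - A @ ui) / bnorm)
            raise NumericalError(
                f"conjugate-gradient solve did not converge (info={info})",
                residual=res,
            )
    if bnorm > 0.0:
        res = float(np.linalg.norm(b - A @ ui) / bnorm)
        if res > FD_RESIDUAL_TOL:
            raise NumericalError(
                "finite-difference solve residual above tolerance",
                residual=res,
            )
    u = np.zeros((n, n))
    u[1:-1, 1:-1] = ui.reshape(ni, ni)
    return VelocityProfile(
        u_um_per_s=u * M_PER_S_TO_UM_PER_S,
        y_m=y,
        z_m=z,
        Ly_m=Ly,
        Lz_m=Lz,
        dpdx_Pa_per_m=dpdx_Pa_per_m,
        provenance="finite-difference",
    )


def back_calculate_dpdx(
    target_umax_um_per_s: float,
    geometry: ChannelGeometry,
    fluid: FluidProperties | None = None,
    cfg: SeriesConfig | None = None,
    solver: str = "series",
) -> float:
    """Pressure gradient whose profile peaks at the target velocity.

    Exact by linearity: solve once at unit (negative) gradient and rescale.
    The returned gradient is negative — pressure falls along the flow.
    """
    if not target_umax_um_per_s > 0:
        raise InvalidInputError("target u_max must be positive")
    if solver == "series":
        unit = series_profile(geometry, -1.0, fluid, cfg)
    elif solver == "fd":
        grid = cfg.grid_points_per_axis if cfg else 129
        unit = fd_poisson_profile(geometry, -1.0, fluid, grid)
    else:
        raise ConfigError(f"unknown solver {solver!r}")
    return -target_umax_um_per_s / unit.u_max_um_per_s


def profile_stats(profile: VelocityProfile) -> ProfileStats:
    """Peak, mean (2D trapezoid), max/mean ratio and flow rate of a profile."""
    u = profile.u_um_per_s
    umax = float(u.max())
    area = profile.Ly_m * profile.Lz_m
    integral = np.trapezoid(
        np.trapezoid(u, profile.z_m, axis=1), profile.y_m
    )  # μm/s · m²
    umean = float(integral / area)
    flow_uL_per_s = float(integral * 1e-6 * 1e9)  # μm/s·m² -> m³/s -> μL/s
    ratio = umax / umean if umean > 0 else 0.0
    return ProfileStats(
        u_max_um_per_s=umax,
        u_mean_um_per_s=umean,
        max_to_mean_ratio=ratio,
        flow_rate_uL_per_s=flow_uL_per_s,
    )


def max_to_mean_ratio(
    geometry: ChannelGeometry,
    fluid: FluidProperties | None = None,
    cfg: SeriesConfig | None = None,
) -> float:
    """Computed u_max/u_mean for the duct aspect ratio (≈ 2.096 if square)."""
    prof = series_profile(geometry, -1.0, fluid, cfg)
    return profile_stats(prof).max_to_mean_ratio


def profile_frame(profile: VelocityProfile):
    """Long-format (y_m, z_m, u_um_per_s) table for CSV export."""
    import pandas as pd

    Y, Z = np.meshgrid(profile.y_m, profile.z_m, indexing="ij")
    return pd.DataFrame(
        {
            "y_m": Y.ravel(),
            "z_m": Z.ravel(),
            "u_um_per_s": profile.u_um_per_s.ravel(),
        }
    )
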