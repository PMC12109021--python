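"""Bulk flow characterization of a pressure-driven perfusion loop.

A bench characterization of a perfusion bioreactor proceeds by collecting
perfusate at the outlet for a timed interval at each drive pressure,
weighing it, and converting the mass flow rate into a volumetric flow rate

    V = M / ρ,

then into the mean velocity through the sample chamber

    u_avg = V / A_c,

and finally into a Reynolds number

    Re = ρ · u_avg · D / μ,

with D the conduit's hydraulic diameter.  Re < 2000 marks laminar flow and
Re < 1 the creeping (Stokes) regime in which the axial momentum balance
reduces to a Poisson problem (see :mod:`perfusionkit.duct`).

This module turns replicated mass-collection measurements into a flow table
(one row per drive pressure: V, u_avg, u_max, τ_max, Re ± propagated SD),
and evaluates the drive-pressure budget

    ΔP = (P_atm + P_hs,fresh + P_d) − (P_atm + P_hs,waste) ≈ P_d,

quantifying how fast the hydrostatic heads in the fresh and waste bottles
erode the drive pressure as fluid is transferred.

Unit conventions
----------------
All computation is SI; report-facing quantities use psi, μL/s and μm/s.
One caveat is deliberate: the hydraulic diameter defaults to the magnitude
0.435 carried with an ``"as-printed"`` unit tag.  Treated as a meter-scale
magnitude it reproduces the reference Reynolds number 0.80 at 1 psi, but it
is physically inconsistent with a ~1 cm chamber (whose hydraulic diameter
is 0.01 m).  The tag keeps that choice visible instead of silently baked in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, StateError
from .units import (
    G_STANDARD,
    m3s_to_uls,
    ms_to_ums,
    pa_to_psi,
    psi_to_pa,
    ums_to_ms,
)

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Density and dynamic viscosity of the perfusate.

    Defaults are DMEM supplemented with FBS at incubation temperature:
    ρ = 1009 kg/m³, μ = 9.30 × 10⁻⁴ Pa·s.
    """

    density_kg_m3: float = 1009.0
    viscosity_Pa_s: float = 9.30e-4

    def __post_init__(self):
        if not (self.density_kg_m3 > 0 and self.viscosity_Pa_s > 0):
            raise InvalidInputError(
                "density and viscosity must be strictly positive"
            )


@dataclass(frozen=True)
class ChannelGeometry:
    """Sample-chamber cross-section and hydraulic diameter.

    ``cross_section_area_Ac_m2`` is settable independently of
    ``width_Ly_m × height_Lz_m`` because the bioreactor's flow cross-section
    (default 2.37 × 10⁻⁴ m², back-derived from the reference flow table) is
    larger than the 10 mm × 10 mm tissue chamber used for the velocity
    profile; :attr:`area_consistent` records whether the two agree.

    ``hydraulic_diameter_D`` carries an explicit unit tag.  The default
    magnitude 0.435 with tag ``"as-printed"`` is used as an SI (meter-scale)
    value in the Reynolds number because only that reading reproduces the
    reference Re = 0.80; it is *not* the geometric 4·A/P of the chamber.
    """

    width_Ly_m: float = 0.01
    height_Lz_m: float = 0.01
    cross_section_area_Ac_m2: float = 2.37e-4
    hydraulic_diameter_D: float = 0.435
    hydraulic_diameter_unit: str = "as-printed"

    def __post_init__(self):
        for name in (
            "width_Ly_m",
            "height_Lz_m",
            "cross_section_area_Ac_m2",
            "hydraulic_diameter_D",
        ):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")

    @property
    def area_consistent(self) -> bool:
        """Whether Ac equals width × height (relative tolerance 1e-9)."""
        return math.isclose(
            self.cross_section_area_Ac_m2,
            self.width_Ly_m * self.height_Lz_m,
            rel_tol=1e-9,
        )


@dataclass(frozen=True)
class MassFlowMeasurement:
    """One timed mass collection at a given drive pressure."""

    drive_pressure_psi: float
    collected_mass_kg: float
    collection_time_s: float
    replicate_id: str = ""

    def __post_init__(self):
        if self.collected_mass_kg < 0:
            raise InvalidInputError("collected mass must be non-negative")
        if not self.collection_time_s > 0:
            raise InvalidInputError("collection time must be positive")
        if not self.drive_pressure_psi > 0:
            raise InvalidInputError("drive pressure must be positive")


@dataclass(frozen=True)
class PressureBudget:
    """Terms of the effective pressure gradient across the loop.

    Hydrostatic terms are *changes relative to the start of the run*:
    transferring fluid lowers the fresh-bottle head (negative term) and
    raises the waste-bottle head (positive term), so

        effective = (atm + hydrostatic_fresh + drive)
                    − (atm + hydrostatic_waste).
    """

    atmospheric_Pa: float
    hydrostatic_fresh_Pa: float
    hydrostatic_waste_Pa: float
    drive_Pa: float
    effective_gradient_Pa: float
    effective_gradient_psi: float
    hydrostatic_sensitivity_psi_per_mL: float


class ReynoldsResult(NamedTuple):
    value: float
    regime: str


class ShearStressResult(NamedTuple):
    """Maximum wall shear stress with its parallel-plate cross-check."""

    tau_max_Pa: float
    tau_parallel_plate_Pa: float


@dataclass(frozen=True)
class FlowParameters:
    """One flow-table row: quantities at a single drive pressure.

    ``reynolds`` follows Re = ρ·u_avg·D/μ; ``reynolds_from_umax`` applies the
    same formula to u_max.  Both are carried because published tables mix
    the two conventions between rows, and the discrepancy should stay
    visible in any rendered output.
    """

    drive_pressure_psi: float
    volumetric_flow_uL_per_s: float
    volumetric_flow_sd: float
    u_avg_um_per_s: float
    u_avg_sd: float
    u_max_um_per_s: float
    u_max_sd: float
    tau_max_Pa: float
    reynolds: float
    reynolds_from_umax: float
    regime: str
    n_replicates: int
    single_replicate: bool = False

    def __post_init__(self):
        vals = (
            self.volumetric_flow_uL_per_s,
            self.u_avg_um_per_s,
            self.u_max_um_per_s,
            self.tau_max_Pa,
            self.reynolds,
        )
        if any(v < 0 for v in vals):
            raise InvalidInputError("flow parameters must be non-negative")
        if self.u_max_um_per_s + 1e-12 < self.u_avg_um_per_s:
            raise InvalidInputError("u_max must be >= u_avg")
        if (self.reynolds == 0) != (self.u_avg_um_per_s == 0):
            raise InvalidInputError("Re vanishes exactly when u_avg does")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def mass_to_volumetric(
    measurement: MassFlowMeasurement, fluid: FluidProperties
) -> float:
    """Volumetric flow rate V = (m/t)/ρ in m³/s.

    Use :func:`perfusionkit.units.m3s_to_uls` to render in μL/s.
    """
    return (
        measurement.collected_mass_kg
        / measurement.collection_time_s
        / fluid.density_kg_m3
    )


def drive_pressure_budget(
    drive_psi: float,
    bottle_area_fresh_m2: float,
    bottle_area_waste_m2: float,
    volume_transferred_m3: float,
    fluid: FluidProperties,
    atmospheric_Pa: float = 101325.0,
) -> PressureBudget:
    """Evaluate the pressure budget after transferring a volume of perfusate.

    The hydrostatic head change in each bottle is ρ·g·(volume/area); the
    fresh bottle loses head, the waste bottle gains it, so both act to
    reduce the effective gradient below the drive pressure.  The returned
    sensitivity (psi per mL transferred) quantifies how negligible the
    hydrostatic contribution is for given bottle cross-sections.
    """
    if not (bottle_area_fresh_m2 > 0 and bottle_area_waste_m2 > 0):
        raise InvalidInputError("bottle areas must be positive")
    if volume_transferred_m3 < 0:
        raise InvalidInputError("transferred volume must be non-negative")
    rho_g = fluid.density_kg_m3 * G_STANDARD
    hs_fresh = -rho_g * volume_transferred_m3 / bottle_area_fresh_m2
    hs_waste = rho_g * volume_transferred_m3 / bottle_area_waste_m2
    drive_Pa = psi_to_pa(drive_psi)
    # atmospheric pressure acts on both bottles and cancels algebraically;
    # computing the cancelled form keeps the zero-transfer case exact
    effective = drive_Pa + (hs_fresh - hs_waste)
    sens = pa_to_psi(
        rho_g * 1e-6 * (1.0 / bottle_area_fresh_m2 + 1.0 / bottle_area_waste_m2)
    )
    return PressureBudget(
        atmospheric_Pa=atmospheric_Pa,
        hydrostatic_fresh_Pa=hs_fresh,
        hydrostatic_waste_Pa=hs_waste,
        drive_Pa=drive_Pa,
        effective_gradient_Pa=effective,
        effective_gradient_psi=pa_to_psi(effective),
        hydrostatic_sensitivity_psi_per_mL=sens,
    )


def average_velocity(volumetric_m3_s: float, geometry: ChannelGeometry) -> float:
    """Mean chamber velocity u_avg = V/Ac, returned in μm/s."""
    if not geometry.cross_section_area_Ac_m2 > 0:
        raise InvalidInputError("cross-sectional area must be positive")
    return ms_to_ums(volumetric_m3_s / geometry.cross_section_area_Ac_m2)


def max_velocity(
    u_avg_um_per_s: float,
    mode: str = "table1",
    geometry: ChannelGeometry | None = None,
    fluid: FluidProperties | None = None,
) -> float:
    """Peak chamber velocity from the mean, in μm/s.

    ``table1`` mode applies the circular-pipe factor u_max = 2·u_avg used by
    the reference characterization.  ``rect-duct`` mode uses the computed
    max/mean ratio of the rectangular-duct profile for the configured
    chamber aspect ratio (≈ 2.096 for a square chamber).
    """
    if u_avg_um_per_s < 0:
        raise InvalidInputError("u_avg must be non-negative")
    if mode == "table1":
        return 2.0 * u_avg_um_per_s
    if mode == "rect-duct":
        from . import duct

        geometry = geometry or ChannelGeometry()
        fluid = fluid or FluidProperties()
        return u_avg_um_per_s * duct.max_to_mean_ratio(geometry, fluid)
    raise ConfigError(f"unknown velocity-ratio mode {mode!r}")


def classify_regime(reynolds_value: float) -> str:
    if reynolds_value < 1.0:
        return "creeping"
    if reynolds_value < 2000.0:
        return "laminar"
    return "non-laminar"


def reynolds(
    u_um_per_s: float, geometry: ChannelGeometry, fluid: FluidProperties
) -> ReynoldsResult:
    """Re = ρ·u·D/μ with a flow-regime classification attached.

    ``u`` is in μm/s; ``D`` is taken at its tagged magnitude (see
    :class:`ChannelGeometry` on the ``as-printed`` caveat).
    """
    if u_um_per_s < 0:
        raise InvalidInputError("velocity must be non-negative")
    re = (
        fluid.density_kg_m3
        * ums_to_ms(u_um_per_s)
        * geometry.hydraulic_diameter_D
        / fluid.viscosity_Pa_s
    )
    return ReynoldsResult(value=re, regime=classify_regime(re))


def wall_shear_stress(profile, fluid: FluidProperties) -> ShearStressResult:
    """Maximum wall shear stress μ·max|∂U/∂n| from a solved velocity profile.

    The normal derivative at each of the four walls is estimated by a
    second-order one-sided difference.  A parallel-plate closed-form
    estimate 6μV/(Ly·Lz²) is returned alongside; the two agree for wide
    ducts but the closed form underestimates τ_max by ~36% in a square
    chamber, so it is a cross-check, not a substitute.

    Parameters
    ----------
    profile : perfusionkit.duct.VelocityProfile
        Solved on a grid of at least 33 points per axis.
    """
    u = getattr(profile, "u_um_per_s", None)
    if u is None:
        raise StateError("profile has no solved velocity field")
    u = np.asarray(u, dtype=float)
    if min(u.shape) < 33:
        raise StateError(
            "wall-derivative estimate requires >= 33 grid points per axis"
        )
    mu = fluid.viscosity_Pa_s
    usi = u / 1e6  # μm/s -> m/s
    hy = profile.y_m[1] - profile.y_m[0]
    hz = profile.z_m[1] - profile.z_m[0]
    # second-order one-sided normal derivatives on each wall
    derivs = [
        np.abs(4.0 * usi[1, :] - usi[2, :]) / (2.0 * hy),
        np.abs(4.0 * usi[-2, :] - usi[-3, :]) / (2.0 * hy),
        np.abs(4.0 * usi[:, 1] - usi[:, 2]) / (2.0 * hz),
        np.abs(4.0 * usi[:, -2] - usi[:, -3]) / (2.0 * hz),
    ]
    tau_max = mu * max(float(d.max()) for d in derivs)
    flow = np.trapezoid(np.trapezoid(usi, profile.z_m, axis=1), profile.y_m)
    tau_pp = 6.0 * mu * flow / (profile.Ly_m * profile.Lz_m**2)
    return ShearStressResult(tau_max_Pa=tau_max, tau_parallel_plate_Pa=tau_pp)


FLOW_TABLE_COLUMNS = [
    "pressure_psi",
    "V_uL_per_s",
    "V_sd",
    "u_avg_um_per_s",
    "u_avg_sd",
    "u_max_um_per_s",
    "u_max_sd",
    "tau_max_Pa",
    "Re",
    "Re_from_umax",
    "regime",
    "n_replicates",
    "single_replicate",
]


def build_flow_table(
    measurements: Iterable[MassFlowMeasurement],
    geometry: ChannelGeometry | None = None,
    fluid: FluidProperties | None = None,
    mode: str = "table1",
    shear_grid_points: int = 129,
) -> list[FlowParameters]:
    """Reduce replicated measurements to one flow-parameter row per pressure.

    Per pressure: mean ± sample SD of V across replicates, then u_avg,
    u_max (per ``mode``), τ_max from the duct profile back-calculated to
    that row's u_max, and Re in both conventions.  SDs propagate by the
    linear scale factors only.  Rows are sorted by pressure so the result
    is invariant to the order of the input replicates.
    """
    geometry = geometry or ChannelGeometry()
    fluid = fluid or FluidProperties()
    ms = list(measurements)
    if not ms:
        raise InvalidInputError("no measurements supplied")
    if mode not in ("table1", "rect-duct"):
        raise ConfigError(f"unknown velocity-ratio mode {mode!r}")
    from . import duct

    by_pressure: dict[float, list[MassFlowMeasurement]] = {}
    for m in ms:
        by_pressure.setdefault(m.drive_pressure_psi, []).append(m)

    rows = []
    for p in sorted(by_pressure):
        reps = by_pressure[p]
        v = np.array([mass_to_volumetric(m, fluid) for m in reps])
        v_mean = float(v.mean())
        single = len(v) == 1
        v_sd = 0.0 if single else float(v.std(ddof=1))
        u_avg = average_velocity(v_mean, geometry)
        u_avg_sd = average_velocity(v_sd, geometry) if v_sd else 0.0
        ratio = (
            2.0
            if mode == "table1"
            else duct.max_to_mean_ratio(geometry, fluid)
        )
        u_max = ratio * u_avg
        u_max_sd = ratio * u_avg_sd
        if u_max > 0:
            dpdx = duct.back_calculate_dpdx(u_max, geometry, fluid)
            prof = duct.series_profile(
                geometry,
                dpdx,
                fluid,
                duct.SeriesConfig(grid_points_per_axis=shear_grid_points),
            )
            tau = wall_shear_stress(prof, fluid).tau_max_Pa
        else:
            tau = 0.0
        re = reynolds(u_avg, geometry, fluid)
        re_umax = reynolds(u_max, geometry, fluid)
        rows.append(
            FlowParameters(
                drive_pressure_psi=p,
                volumetric_flow_uL_per_s=m3s_to_uls(v_mean),
                volumetric_flow_sd=m3s_to_uls(v_sd),
                u_avg_um_per_s=u_avg,
                u_avg_sd=u_avg_sd,
                u_max_um_per_s=u_max,
                u_max_sd=u_max_sd,
                tau_max_Pa=tau,
                reynolds=re.value,
                reynolds_from_umax=re_umax.value,
                regime=re.regime,
                n_replicates=len(v),
                single_replicate=single,
            )
        )
    return rows


def flow_table_frame(rows: Sequence[FlowParameters]) -> pd.DataFrame:
    """Render flow-parameter rows as the flow-table CSV layout."""
    return pd.DataFrame(
        [
            {
                "pressure_psi": r.drive_pressure_psi,
                "V_uL_per_s": r.volumetric_flow_uL_per_s,
                "V_sd": r.volumetric_flow_sd,
                "u_avg_um_per_s": r.u_avg_um_per_s,
                "u_avg_sd": r.u_avg_sd,
                "u_max_um_per_s": r.u_max_um_per_s,
                "u_max_sd": r.u_max_sd,
                "tau_max_Pa": r.tau_max_Pa,
                "Re": r.reynolds,
                "Re_from_umax": r.reynolds_from_umax,
                "regime": r.regime,
                "n_replicates": r.n_replicates,
                "single_replicate": r.single_replicate,
            }
            for r in rows
        ],
        columns=FLOW_TABLE_COLUMNS,
    )
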