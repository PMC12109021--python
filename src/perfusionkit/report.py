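"""End-to-end characterization report.

Orchestrates the stages into one run: read timed mass-collection
measurements, build the flow table, back-calculate the pressure gradient
from the lowest-pressure peak velocity, solve the chamber velocity
profile, and emit a single machine-readable report.  Two runs with
identical inputs produce identical JSON (no timestamps are recorded —
provenance is the config hash and seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .duct import (
    back_calculate_dpdx,
    profile_frame,
    profile_stats,
    series_profile,
)
from .errors import ParseError
from .flow import (
    FlowParameters,
    MassFlowMeasurement,
    build_flow_table,
    flow_table_frame,
)

MEASUREMENT_COLUMNS = ["pressure_psi", "mass_g", "time_s", "replicate"]

REPORT_REQUIRED_KEYS = {
    "package_version": str,
    "config_hash": str,
    "seed": int,
    "flow_table": list,
    "profile_summary": dict,
    "regimes": dict,
    "notes": list,
}


def load_measurements(path) -> list[MassFlowMeasurement]:
    """Parse a measurement CSV (pressure_psi, mass_g, time_s, replicate).

    Raises :class:`ParseError` naming the offending row on malformed or
    non-physical entries, and on an empty table.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: no measurement rows")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                MassFlowMeasurement(
                    drive_pressure_psi=float(row["pressure_psi"]),
                    collected_mass_kg=float(row["mass_g"]) / 1e3,
                    collection_time_s=float(row["time_s"]),
                    replicate_id=str(row.get("replicate", idx)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: row {idx}: {exc}") from exc
    return out


def validate_report(report: dict) -> dict:
    """Schema check for the report bundle; returns the report unchanged."""
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in report:
            raise ParseError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ParseError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    return report


def run_characterization(
    measurements_path, config: RunConfig, out_dir
) -> dict:
    """Run the full flow characterization and write the report bundle.

    Writes ``flow_table.csv``, ``profile_grid.csv``, ``profile_summary.json``
    and ``report.json`` under ``out_dir`` and returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    measurements = load_measurements(measurements_path)
    rows = build_flow_table(
        measurements,
        geometry=config.geometry,
        fluid=config.fluid,
        mode=config.velocity_ratio_mode,
        shear_grid_points=config.series.grid_points_per_axis,
    )
    table = flow_table_frame(rows)
    table.to_csv(out / "flow_table.csv", index=False, float_format="%.12g")

    # profile driven by the lowest-pressure peak velocity
    lowest: FlowParameters = rows[0]
    summary: dict = {}
    if lowest.u_max_um_per_s > 0:
        dpdx = back_calculate_dpdx(
            lowest.u_max_um_per_s, config.geometry, config.fluid, config.series
        )
        profile = series_profile(
            config.geometry, dpdx, config.fluid, config.series
        )
        stats = profile_stats(profile)
        profile_frame(profile).to_csv(
            out / "profile_grid.csv", index=False, float_format="%.12g"
        )
        summary = {
            "dpdx_Pa_per_m": dpdx,
            "u_max_um_per_s": stats.u_max_um_per_s,
            "u_mean_um_per_s": stats.u_mean_um_per_s,
            "max_to_mean_ratio": stats.max_to_mean_ratio,
            "flow_rate_uL_per_s": stats.flow_rate_uL_per_s,
            "back_calculated_from_pressure_psi": lowest.drive_pressure_psi,
        }
        (out / "profile_summary.json").write_text(
            json.dumps(summary, indent=2)
        )

    report = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "flow_table": table.to_dict(orient="records"),
        "profile_summary": summary,
        "regimes": {
            f"{r.drive_pressure_psi:g}_psi": r.regime for r in rows
        },
        "notes": [
            "Re column follows Re = rho*u_avg*D/mu; Re_from_umax applies the "
            "same formula to u_max. Published tables mix the two conventions "
            "between rows; both are reported so the discrepancy stays visible.",
            "hydraulic diameter D is used at its as-printed magnitude "
            "(see ChannelGeometry docs).",
        ],
    }
    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
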