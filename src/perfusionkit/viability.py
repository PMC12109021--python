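"""Live/dead viability gating and two-sample Welch statistics.

Cell viability after perfusion is read out with an amine-reactive
live/dead stain: dead cells bind more dye and fluoresce more strongly.
The gate separating live from dead is calibrated on a positive control —
an aliquot deliberately killed with 70% ethanol — by taking a low empirical
quantile (default 1%) of the control's intensities as the dead threshold,
so at least 99% of the control is classified dead by construction.  This
is a deterministic, reproducible surrogate for manual gating in a
cytometry GUI.

Group comparisons use the unequal-variance (Welch) two-sample t-test:

    t  = (x̄_a − x̄_b) / √(s_a²/n_a + s_b²/n_b)
    df = (s_a²/n_a + s_b²/n_b)² /
         [(s_a²/n_a)²/(n_a−1) + (s_b²/n_b)²/(n_b−1)]

with a two-tailed p from Student's t distribution.  The Welch form is the
default because fractional degrees of freedom are what published viability
comparisons in this setting report; a pooled-variance option exists behind
a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError


@dataclass(frozen=True)
class EventTable:
    """Per-event fluorescence intensities for one sample."""

    intensity: np.ndarray
    sample_label: str = ""
    condition: str = ""  # perfused | static | killed_control

    def __post_init__(self):
        x = np.asarray(self.intensity, dtype=float)
        if x.size < 1:
            raise InvalidInputError("event table must contain >= 1 event")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise InvalidInputError("intensities must be finite and >= 0")
        object.__setattr__(self, "intensity", x)

    @property
    def n_events(self) -> int:
        return self.intensity.size


@dataclass(frozen=True)
class GatingModel:
    """Dead/live intensity threshold calibrated on a killed control."""

    dead_threshold: float
    control_quantile: float = 0.01
    control_label: str = "killed_control"

    def __post_init__(self):
        if not self.dead_threshold > 0:
            raise InvalidInputError("dead threshold must be positive")
        if not (0 < self.control_quantile <= 0.5):
            raise InvalidInputError("control quantile must be in (0, 0.5]")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD of a percentage across n replicates."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InvalidInputError("group summaries need n >= 2")
        if self.sd < 0:
            raise InvalidInputError("sd must be non-negative")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_tailed: float


def fit_gate(
    control: EventTable, quantile: float = 0.01
) -> GatingModel:
    """Dead threshold = the given empirical quantile of the killed control.

    Events at or above the threshold are classified dead, so at least
    (1 − quantile) of the control is called dead.
    """
    if control.n_events < 100:
        raise InvalidInputError(
            "gate calibration needs >= 100 control events"
        )
    thr = float(np.quantile(control.intensity, quantile))
    return GatingModel(
        dead_threshold=thr,
        control_quantile=quantile,
        control_label=control.sample_label or "killed_control",
    )


def percent_live(sample: EventTable, gate: GatingModel) -> float:
    """100 × fraction of events below the dead threshold."""
    return 100.0 * float(
        np.mean(sample.intensity < gate.dead_threshold)
    )


def percent_dead(sample: EventTable, gate: GatingModel) -> float:
    return 100.0 - percent_live(sample, gate)


def welch_from_summary(
    a: GroupSummary, b: GroupSummary, pooled: bool = False
) -> WelchResult:
    """Two-tailed two-sample t-test from group summaries.

    Welch's unequal-variance form by default; ``pooled=True`` gives the
    classical equal-variance Student test (df = n_a + n_b − 2).
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            # identical degenerate groups: no evidence of difference
            return WelchResult(t=0.0, df=float(a.n + b.n - 2), p_two_tailed=1.0)
        raise InvalidInputError(
            "both groups have zero variance but different means"
        )
    if pooled:
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va**2 / (a.n - 1) + vb**2 / (b.n - 1)
        )
    t = (a.mean - b.mean) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p_two_tailed=min(p, 1.0))


def summarize(values) -> GroupSummary:
    """Mean, sample SD (n−1 denominator) and n of replicate percentages."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need >= 2 replicates to summarize")
    return GroupSummary(
        mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size)
    )


def welch_from_samples(x, y, pooled: bool = False) -> WelchResult:
    """Welch test on two lists of replicate percentages.

    Identical (to floating point) to :func:`welch_from_summary` applied to
    the lists' means and sample SDs.
    """
    return welch_from_summary(summarize(x), summarize(y), pooled=pooled)
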