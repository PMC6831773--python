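"""Water-chemistry computations for the flow-through columns.

Daily influent/effluent NH4+, NO2- and NO3- concentrations (uM N) yield
removal/accretion percentages and a nitrogen mass-balance test.  Nitrite and
nitrate are transient/terminal products of nitrification, so their removal
and accretion are normalised by the amount *produced* upstream (ammonium
removed, or influent nitrite for nitrite-fed columns), not by influent
concentration.  Effluent nitrite is corrected for the trace NO2- present in
the feed water (~0.3 uM) before computing removal.

The mass balance tests whether total N out equals total N in: sigma_day =
(effluent N) - (influent N); a one-sample two-tailed t test of the daily
sigma series against zero declares the balance closed when p >= alpha.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import ChemistryRecord

__all__ = [
    "NOT_DETERMINED",
    "ProducedFrom",
    "TRACE_NO2_UM",
    "nh4_removal",
    "no2_removal",
    "no3_accretion",
    "mass_balance",
    "summarize_column",
    "PerformanceSummary",
]

#: Sentinel for percentages that cannot be computed ("ND" in reporting).
NOT_DETERMINED = float("nan")

#: Trace nitrite concentration in the feed water, uM.
TRACE_NO2_UM = 0.3


class ProducedFrom(str, enum.Enum):
    """Which upstream pool the produced NO2-/NO3- is estimated from."""

    FROM_NH4 = "FROM_NH4"  # produced N = ammonium removed
    FROM_INFLUENT = "FROM_INFLUENT"  # produced NO2- = influent NO2- (NO2-fed)
    FROM_NO2 = "FROM_NO2"  # produced NO3- = nitrite removed (NO2-fed)


def nh4_removal(rec: ChemistryRecord) -> float:
    """NH4+ removal %: 100 * (influent - effluent) / influent.

    Returns NOT_DETERMINED (NaN) when influent NH4+ is zero.
    """
    if rec.nh4_in <= 0:
        return NOT_DETERMINED
    return 100.0 * (rec.nh4_in - rec.nh4_out) / rec.nh4_in


def no2_removal(
    rec: ChemistryRecord,
    mode: ProducedFrom = ProducedFrom.FROM_NH4,
    trace_no2: float = TRACE_NO2_UM,
) -> float:
    """NO2- removal %: produced minus trace-corrected effluent, over produced.

    Produced NO2- is the ammonium removed (FROM_NH4) or the influent NO2-
    (FROM_INFLUENT, for nitrite-fed columns).  Effluent NO2- is corrected by
    subtracting the feed-water trace (floored at zero).  Returns
    NOT_DETERMINED when nothing was produced.
    """
    if mode is ProducedFrom.FROM_NH4:
        produced = rec.nh4_in - rec.nh4_out
    elif mode is ProducedFrom.FROM_INFLUENT:
        produced = rec.no2_in
    else:
        raise ValueError(f"invalid mode for no2_removal: {mode}")
    if produced <= 0:
        return NOT_DETERMINED
    effluent = max(rec.no2_out - trace_no2, 0.0)
    return 100.0 * (produced - effluent) / produced


def no3_accretion(
    rec: ChemistryRecord,
    mode: ProducedFrom = ProducedFrom.FROM_NH4,
    measurement_sd: float = 1.0,
) -> float:
    """NO3- accretion %: effluent minus influent NO3-, over produced NO3-.

    Produced NO3- is the ammonium removed (FROM_NH4) or the nitrite removed
    (FROM_NO2, for nitrite-fed columns).  Returns NOT_DETERMINED when nothing
    was produced or when |effluent - influent| is below the detection floor
    (2x the measurement sd, default 1 uM) — the "ND" of reporting tables.
    """
    if mode is ProducedFrom.FROM_NH4:
        produced = rec.nh4_in - rec.nh4_out
    elif mode is ProducedFrom.FROM_NO2:
        produced = rec.no2_in - rec.no2_out
    else:
        raise ValueError(f"invalid mode for no3_accretion: {mode}")
    if produced <= 0:
        return NOT_DETERMINED
    delta = rec.no3_out - rec.no3_in
    if abs(delta) < 2.0 * measurement_sd:
        return NOT_DETERMINED
    return 100.0 * delta / produced


@dataclass
class PerformanceSummary:
    """Per-column chemistry summary: percentages (mean +/- sd over days),
    daily N-balance residuals, and the mass-balance verdict."""

    column_id: str
    nh4_removal_pct: tuple[float, float]  # (mean, sd); NaN if ND throughout
    no2_removal_pct: tuple[float, float]
    no3_accretion_pct: tuple[float, float]
    sigma_series: list[float] = field(default_factory=list)  # per-day, uM N
    balance_closed: bool = True
    p_value: float = 1.0
    t_statistic: float = 0.0


def mass_balance(
    series: list[ChemistryRecord],
    alpha: float = 0.05,
    column_id: str = "column_1",
) -> PerformanceSummary:
    """Daily N balance sigma = effluent N - influent N, tested against zero.

    A one-sample two-tailed t test on the sigma series; the balance is closed
    when the test does not reject (p >= alpha).  A zero-variance, all-zero
    sigma series is trivially closed.  Requires >= 3 days.
    """
    if len(series) < 3:
        raise ValueError(f"mass balance needs >= 3 days, got {len(series)}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    sigma = np.array([r.total_n_out - r.total_n_in for r in series])
    if np.allclose(np.std(sigma), 0.0):
        closed = bool(np.allclose(sigma, 0.0))
        t_stat, p = (0.0, 1.0) if closed else (math.inf, 0.0)
    else:
        t_stat, p = stats.ttest_1samp(sigma, 0.0)
        closed = bool(p >= alpha)
    return PerformanceSummary(
        column_id=column_id,
        nh4_removal_pct=(NOT_DETERMINED, NOT_DETERMINED),
        no2_removal_pct=(NOT_DETERMINED, NOT_DETERMINED),
        no3_accretion_pct=(NOT_DETERMINED, NOT_DETERMINED),
        sigma_series=[float(s) for s in sigma],
        balance_closed=closed,
        p_value=float(p),
        t_statistic=float(t_stat),
    )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.array([v for v in values if not math.isnan(v)])
    if arr.size == 0:
        return (NOT_DETERMINED, NOT_DETERMINED)
    return (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)


def summarize_column(
    series: list[ChemistryRecord],
    column_id: str = "column_1",
    no2_mode: ProducedFrom = ProducedFrom.FROM_NH4,
    no3_mode: ProducedFrom = ProducedFrom.FROM_NH4,
    alpha: float = 0.05,
    trace_no2: float = TRACE_NO2_UM,
    measurement_sd: float = 1.0,
) -> PerformanceSummary:
    """Full per-column summary: daily percentages aggregated as mean +/- sd
    over days, plus the mass-balance test."""
    summary = mass_balance(series, alpha=alpha, column_id=column_id)
    summary.nh4_removal_pct = _mean_sd([nh4_removal(r) for r in series])
    summary.no2_removal_pct = _mean_sd(
        [no2_removal(r, no2_mode, trace_no2) for r in series]
    )
    summary.no3_accretion_pct = _mean_sd(
        [no3_accretion(r, no3_mode, measurement_sd) for r in series]
    )
    return summary
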