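"""Per-curve growth statistics.

Relative growth rate (RGR), coefficient-of-variation dynamics across
genotypes, water-use efficiency (WUE) per stress phase, and the
timing/magnitude of the biomass decline around maximum water stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridError, GrowthDynError
from .io import GrowthCurve, TraitTable, genotype_means

__all__ = [
    "relative_growth_rate",
    "rgr_series",
    "cv_series",
    "wue",
    "decline_metrics",
    "DeclineMetrics",
]


def relative_growth_rate(w1: float, w2: float, t1: float, t2: float) -> float:
    """RGR = (ln W2 - ln W1) / (T2 - T1), in day^-1.

    W1, W2 are biomass at days T1 < T2; natural logarithm.
    """
    if w1 <= 0 or w2 <= 0:
        raise GrowthDynError(
            "biomass must be positive for RGR", {"w1": w1, "w2": w2}
        )
    if t2 <= t1:
        raise GrowthDynError("t2 must exceed t1", {"t1": t1, "t2": t2})
    return (np.log(w2) - np.log(w1)) / (t2 - t1)


def rgr_series(curve: GrowthCurve) -> pd.Series:
    """RGR per consecutive grid interval.

    Length is ``len(dats) - 1``; an interval spanning a missing imaging
    day (e.g. 29 -> 31) uses the true day distance, so RGR stays per-day.
    Indexed by the interval's end day.
    """
    d = np.asarray(curve.dats, dtype=float)
    w = np.asarray(curve.means, dtype=float)
    if np.any(w <= 0):
        bad = int(np.argmax(w <= 0))
        raise GrowthDynError(
            f"non-positive biomass at interval index {bad}",
            {"interval": bad, "dat": int(d[bad])},
        )
    vals = np.diff(np.log(w)) / np.diff(d)
    return pd.Series(vals, index=curve.dats[1:], name="rgr")


def cv_series(
    table: TraitTable,
    trait: str,
    treatment: str,
    level: str = "genotype",
) -> pd.Series:
    """Percent coefficient of variation per imaging day.

    CV(dat) = 100 * sd / mean, sample sd (n-1 denominator).  By default
    the spread is across *genotype means* (one value per genotype per
    day); ``level='replicate'`` uses all individual plants instead.
    """
    df = table.subset(trait=trait, treatment=treatment)
    if level == "genotype":
        per = df.groupby(["dat", "genotype"])["value"].mean().reset_index()
    elif level == "replicate":
        per = df
    else:
        raise ValueError(f"unknown level {level!r}")
    g = per.groupby("dat")["value"]
    mean, sd, n = g.mean(), g.std(ddof=1), g.size()
    if (n < 2).any():
        raise GrowthDynError("need >= 2 genotypes per day for CV")
    if (mean == 0).any():
        raise GrowthDynError("zero mean; CV undefined")
    out = 100.0 * sd / mean
    out.name = "cv_percent"
    return out


def wue(
    curve: GrowthCurve,
    water_applied: float,
    phase: str = "stress",
    phase_bounds: tuple[int, int] | None = None,
) -> float:
    """Water-use efficiency: biomass gained per gram of water applied.

    Default phase bounds: stress DAT 2 -> 22, recovery DAT 22 -> 35.
    """
    if water_applied <= 0:
        raise GrowthDynError("water_applied must be positive")
    if phase_bounds is None:
        phase_bounds = {"stress": (2, 22), "recovery": (22, 35)}[phase]
    start, end = phase_bounds
    return (curve.value_at(end) - curve.value_at(start)) / water_applied


@dataclass(frozen=True)
class DeclineMetrics:
    """Timing and magnitude of the pre-rewatering biomass decline.

    peak_dat : day of maximum biomass inside the search window
    days_of_decline : trough day minus peak day
    pct_decline : 100 * (peak - trough) / peak, floored at 0
    """

    genotype_id: str
    treatment: str
    peak_dat: int
    days_of_decline: int
    pct_decline: float


def decline_metrics(
    curve: GrowthCurve,
    search_window: tuple[int, int] = (19, 21),
    trough_dat: int = 22,
) -> DeclineMetrics:
    """Locate the growth peak in the window and measure the drop to the
    maximum-stress day.

    The peak is the argmax of the curve within ``search_window`` (ties
    break to the earliest day — the conservative, longest-decline
    choice).  The trough day is fixed at the declared maximum-stress
    day, so a curve still rising through it gets ``pct_decline`` 0.
    """
    if curve.treatment not in ("W", "NW"):
        raise GrowthDynError(
            f"decline metrics only defined in water-stress treatments, "
            f"got {curve.treatment}",
            {"treatment": curve.treatment},
        )
    lo, hi = search_window
    window = [d for d in curve.dats if lo <= d <= hi]
    if not window:
        raise GridError("search window not on curve grid", {"window": [lo, hi]})
    trough = curve.value_at(trough_dat)  # raises if off grid
    vals = [curve.value_at(d) for d in window]
    peak_i = int(np.argmax(vals))  # argmax takes the first maximum
    peak_dat, peak = window[peak_i], vals[peak_i]
    pct = max(0.0, 100.0 * (peak - trough) / peak)
    return DeclineMetrics(
        genotype_id=curve.genotype_id,
        treatment=curve.treatment,
        peak_dat=peak_dat,
        days_of_decline=trough_dat - peak_dat,
        pct_decline=pct,
    )


def decline_table(
    table: TraitTable,
    trait: str = "EBv",
    treatments: tuple[str, ...] = ("W", "NW"),
    search_window: tuple[int, int] = (19, 21),
    trough_dat: int = 22,
) -> pd.DataFrame:
    """Decline metrics for every genotype in the stress treatments."""
    rows = []
    for c in genotype_means(table, trait):
        if c.treatment not in treatments:
            continue
        m = decline_metrics(c, search_window, trough_dat)
        rows.append(
            {
                "genotype": m.genotype_id,
                "treatment": m.treatment,
                "peak_dat": m.peak_dat,
                "days_of_decline": m.days_of_decline,
                "pct_decline": m.pct_decline,
            }
        )
    return pd.DataFrame(rows)
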