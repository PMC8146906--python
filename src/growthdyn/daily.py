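"""Per-day treatment testing, onset-of-significance detection, and
trait-correlation dynamics.

Each imaging day is analysed separately (the day grid is irregular, and
the practice in longitudinal phenotyping is to report per-day
significance without cross-day multiplicity adjustment; output headers
state this).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GrowthDynError
from .io import TraitTable

__all__ = [
    "per_day_treatment_test",
    "onset_detection",
    "OnsetReport",
    "correlation_series",
    "CorrelationSeries",
    "pearson_critical_value",
]


def per_day_treatment_test(
    table: TraitTable, trait: str, dat: int
) -> pd.DataFrame:
    """All-pairwise treatment comparison at one imaging day.

    Fits the one-day linear model ``value ~ treatment + replicate``
    (both fixed) on the genotype-replicate observations, then applies
    Tukey's HSD: the studentized-range statistic on the treatment means
    with the model's residual mean square and degrees of freedom.

    Returns a DataFrame with one row per treatment pair: the mean
    difference, the q statistic, and the Tukey-adjusted p-value.
    """
    df = table.subset(trait=trait)
    df = df[df["dat"] == int(dat)]
    if df.empty:
        raise GrowthDynError(f"no observations for {trait} at DAT {dat}")
    treatments = [t for t in table.treatments if t in set(df["treatment"])]
    k = len(treatments)
    if k < 2:
        raise GrowthDynError("need >= 2 treatments at this day")
    counts = df.groupby("treatment").size()
    if (counts < 2).any():
        raise GrowthDynError(
            "singular design: a treatment has < 2 observations",
            {"counts": counts.to_dict()},
        )
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    # additive fixed-effects design: intercept + treatment + replicate
    X = [np.ones(n)]
    for t in treatments[1:]:
        X.append((df["treatment"] == t).to_numpy(float))
    reps = sorted(df["replicate"].unique())
    for r in reps[1:]:
        X.append((df["replicate"] == r).to_numpy(float))
    X = np.column_stack(X)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfe = n - rank
    if dfe < 1:
        raise GrowthDynError("no residual degrees of freedom")
    mse = float(resid @ resid) / dfe

    means = df.groupby("treatment")["value"].mean()
    ns = counts
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = treatments[i], treatments[j]
            # harmonic-mean group size (Tukey-Kramer for mild imbalance)
            nh = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
            se = np.sqrt(mse / nh)
            diff = means[a] - means[b]
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, dfe)) if np.isfinite(q) else 0.0
            rows.append(
                {"pair": f"{a}-{b}", "diff": diff, "q": q,
                 "p_adj": min(1.0, p), "df": dfe}
            )
    return pd.DataFrame(rows).set_index("pair")


@dataclass(frozen=True)
class OnsetReport:
    """First day a treatment contrast becomes (persistently) significant.

    ``runs`` lists every maximal consecutive span of significant days as
    (start_dat, end_dat) pairs; ``onset_dat`` is the start of the first
    run of length >= the persistence requirement (None if no such run).
    """

    trait: str
    contrast: str
    pvalues: pd.Series
    alpha: float
    persistence: int
    onset_dat: int | None
    runs: list[tuple[int, int]]


def onset_detection(
    pvals: pd.Series,
    alpha: float = 0.05,
    persistence: int = 1,
    trait: str = "",
    contrast: str = "",
) -> OnsetReport:
    """Scan per-day adjusted p-values for the onset of significance.

    ``pvals`` must be indexed by imaging day in increasing order.
    Consecutive means consecutive *grid positions* (the grid is
    irregular, so a run may span a missing calendar day).
    """
    pvals = pvals.sort_index()
    sig = pvals <= alpha
    days = list(pvals.index)
    runs: list[tuple[int, int]] = []
    start = None
    for d, s in zip(days, sig):
        if s and start is None:
            start = d
        elif not s and start is not None:
            runs.append((start, prev))
            start = None
        prev = d
    if start is not None:
        runs.append((start, days[-1]))
    onset = None
    pos = {d: i for i, d in enumerate(days)}
    for s, e in runs:
        if pos[e] - pos[s] + 1 >= persistence:
            onset = s
            break
    return OnsetReport(
        trait=trait,
        contrast=contrast,
        pvalues=pvals,
        alpha=alpha,
        persistence=persistence,
        onset_dat=onset,
        runs=runs,
    )


def onset_for_contrast(
    table: TraitTable,
    trait: str,
    treatment: str,
    reference: str = "C",
    alpha: float = 0.05,
    persistence: int = 1,
) -> OnsetReport:
    """Per-day Tukey tests for one treatment-vs-reference contrast, then
    onset detection on the resulting p-value series."""
    pair = None
    ps = {}
    for dat in table.grid:
        try:
            res = per_day_treatment_test(table, trait, dat)
        except GrowthDynError:
            continue
        for cand in (f"{reference}-{treatment}", f"{treatment}-{reference}"):
            if cand in res.index:
                pair = cand
                ps[dat] = res.loc[cand, "p_adj"]
                break
    if not ps:
        raise GrowthDynError(f"contrast {treatment} vs {reference} never estimable")
    return onset_detection(
        pd.Series(ps), alpha=alpha, persistence=persistence,
        trait=trait, contrast=f"{treatment} vs {reference}",
    )


def pearson_critical_value(n: int, alpha: float = 0.05) -> float:
    """|r| threshold for two-sided significance at level alpha, from
    inverting t = r sqrt(n-2) / sqrt(1-r^2) at the 1-alpha/2 t-quantile
    with n-2 df."""
    if n < 3:
        return np.nan
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


@dataclass(frozen=True)
class CorrelationSeries:
    """Per-day Pearson correlation between two traits across genotypes."""

    trait_x: str
    trait_y: str
    treatment: str
    r: pd.Series
    n: pd.Series
    critical_value: pd.Series
    significant: pd.Series  # flag <=> |r| >= critical value


def correlation_series(
    table: TraitTable,
    trait_x: str,
    trait_y: str = "EBv",
    treatment: str = "C",
    alpha: float = 0.05,
) -> CorrelationSeries:
    """Dynamic trait association: per-day r across genotype means.

    A day where either trait is constant across genotypes yields NaN
    (flagged not-significant), never a fabricated value.
    """
    gx = (
        table.subset(trait=trait_x, treatment=treatment)
        .groupby(["dat", "genotype"])["value"].mean().unstack()
    )
    gy = (
        table.subset(trait=trait_y, treatment=treatment)
        .groupby(["dat", "genotype"])["value"].mean().unstack()
    )
    days = gx.index.intersection(gy.index)
    rs, ns, crits, sig = {}, {}, {}, {}
    for d in days:
        x, y = gx.loc[d], gy.loc[d]
        both = x.notna() & y.notna()
        nn = int(both.sum())
        if nn < 4:
            raise GrowthDynError(f"need >= 4 genotypes with both traits at DAT {d}")
        xv, yv = x[both].to_numpy(), y[both].to_numpy()
        if xv.std(ddof=0) == 0 or yv.std(ddof=0) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(xv, yv)[0, 1])
        crit = pearson_critical_value(nn, alpha)
        rs[d], ns[d], crits[d] = r, nn, crit
        sig[d] = bool(abs(r) >= crit) if np.isfinite(r) else False
    return CorrelationSeries(
        trait_x=trait_x,
        trait_y=trait_y,
        treatment=treatment,
        r=pd.Series(rs, name="r"),
        n=pd.Series(ns, name="n"),
        critical_value=pd.Series(crits, name="r_crit"),
        significant=pd.Series(sig, name="significant"),
    )
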