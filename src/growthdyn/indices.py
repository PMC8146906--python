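"""Drought-adaptive capability indices and their correlations.

For each genotype, three ratios compare the biomass increment under a
water-stress treatment with the matching control increment:

* tolerance  DTO = dEBv_stress(9 -> 22)  / dEBv_control(9 -> 22)
* recovery   DRC = dEBv_stress(23 -> 35) / dEBv_control(23 -> 35)
* adaptability DAD = dEBv_stress(9 -> 35) / dEBv_control(9 -> 35)

Anchor days: stress initiation (9), maximum stress (22), start of
rewatering (23), harvest (35).  Ratios are computed on replicate-mean
genotype curves and reported once per genotype; a window whose control
increment is non-positive yields a missing (never clipped) score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GrowthDynError, UndefinedScoreError
from .io import GrowthCurve, TraitTable, genotype_means
from .metrics import wue

__all__ = [
    "CapabilityScores",
    "capability_scores",
    "capability_table",
    "capability_correlations",
    "trait_capability_table",
    "DEFAULT_ANCHORS",
]

DEFAULT_ANCHORS = {"start": 9, "max_stress": 22, "rewater": 23, "end": 35}

INDEX_NAMES = ("dto", "drc", "dad")


@dataclass(frozen=True)
class CapabilityScores:
    genotype_id: str
    treatment: str  # the stress treatment (W or NW)
    dto: float
    drc: float
    dad: float
    wue_stress: float | None = None
    wue_recovery: float | None = None


def _increment(curve: GrowthCurve, start: int, end: int) -> float:
    return curve.value_at(end) - curve.value_at(start)


def capability_scores(
    stress: GrowthCurve,
    control: GrowthCurve,
    anchors: dict | None = None,
    water_applied: dict | None = None,
) -> CapabilityScores:
    """Tolerance/recovery/adaptability ratios for one genotype.

    Parameters
    ----------
    stress, control : GrowthCurve
        Replicate-mean biomass curves for the same genotype under a
        stress treatment (W/NW) and control (C/N respectively).
    anchors : dict, optional
        ``start``, ``max_stress``, ``rewater``, ``end`` days.
    water_applied : dict, optional
        ``{"stress": grams, "recovery": grams}``; if given, per-phase
        water-use efficiency is attached.

    Raises
    ------
    UndefinedScoreError
        Naming the window whose control increment is <= 0.
    """
    a = {**DEFAULT_ANCHORS, **(anchors or {})}
    windows = {
        "dto": (a["start"], a["max_stress"]),
        "drc": (a["rewater"], a["end"]),
        "dad": (a["start"], a["end"]),
    }
    out = {}
    for name, (s, e) in windows.items():
        denom = _increment(control, s, e)
        if denom <= 0:
            raise UndefinedScoreError(
                f"control increment non-positive in {name} window "
                f"(DAT {s} -> {e})",
                {"index": name, "window": [s, e], "control_increment": denom},
            )
        out[name] = _increment(stress, s, e) / denom
    wue_s = wue_r = None
    if water_applied is not None:
        wue_s = wue(stress, water_applied["stress"], phase_bounds=(2, a["max_stress"]))
        wue_r = wue(stress, water_applied["recovery"], phase_bounds=(a["max_stress"], a["end"]))
    return CapabilityScores(
        genotype_id=stress.genotype_id,
        treatment=stress.treatment,
        dto=out["dto"],
        drc=out["drc"],
        dad=out["dad"],
        wue_stress=wue_s,
        wue_recovery=wue_r,
    )


def capability_table(
    table: TraitTable,
    treatment: str = "W",
    trait: str = "EBv",
    anchors: dict | None = None,
    water_applied: dict | None = None,
) -> pd.DataFrame:
    """Scores for every genotype: stress treatment vs its control.

    W is compared against C and NW against N, so the ratio isolates the
    water effect.  Genotypes with an undefined window get NaN scores.
    """
    control = {"W": "C", "NW": "N"}.get(treatment)
    if control is None:
        raise GrowthDynError(f"{treatment!r} is not a water-stress treatment")
    curves = {(c.genotype_id, c.treatment): c for c in genotype_means(table, trait)}
    rows = []
    for g in table.genotypes:
        sc, cc = curves.get((g, treatment)), curves.get((g, control))
        if sc is None or cc is None:
            continue
        try:
            s = capability_scores(sc, cc, anchors, water_applied)
            rows.append(
                {
                    "genotype": g,
                    "dto": s.dto,
                    "drc": s.drc,
                    "dad": s.dad,
                    "wue_stress": s.wue_stress,
                    "wue_recovery": s.wue_recovery,
                }
            )
        except UndefinedScoreError:
            rows.append({"genotype": g, "dto": np.nan, "drc": np.nan, "dad": np.nan,
                         "wue_stress": np.nan, "wue_recovery": np.nan})
    return pd.DataFrame(rows).set_index("genotype")


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform (n-2 df)."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def capability_correlations(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 Pearson correlation matrix among DTO/DRC/DAD with p-values.

    Columns with no variance are flagged NaN rather than reported as a
    spurious correlation.
    """
    cols = [c for c in INDEX_NAMES if c in scores.columns]
    df = scores[cols].dropna()
    if len(df) < 3:
        raise GrowthDynError(
            f"need >= 3 genotypes with defined scores, got {len(df)}"
        )
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            if df[a].std(ddof=0) == 0 or df[b].std(ddof=0) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = _pearson_with_p(df[a].to_numpy(), df[b].to_numpy())
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def significance_stars(p: float) -> str:
    """The conventional star coding: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if np.isnan(p):
        return ""
    for stars, cut in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
        if p <= cut:
            return stars
    return ""


def trait_capability_table(
    table: TraitTable,
    scores: pd.DataFrame,
    treatment: str,
    traits: list[str] | None = None,
    dats: tuple[int, ...] = (22, 35),
) -> pd.DataFrame:
    """Correlate genotype trait means at key days with DTO/DRC/DAD.

    One row per (trait, dat); columns r and stars per index.  Mirrors
    the convention of reporting trait-capability associations at
    maximum stress and after recovery.
    """
    traits = traits or table.traits
    missing = []
    rows = []
    df = table.subset(treatment=treatment)
    for trait in traits:
        sub = df[df["trait"] == trait]
        for dat in dats:
            at = sub[sub["dat"] == dat]
            if at.empty:
                missing.append((trait, dat))
                continue
            gmeans = at.groupby("genotype")["value"].mean()
            row = {"trait": trait, "dat": dat}
            for idx in INDEX_NAMES:
                merged = pd.concat([gmeans, scores[idx]], axis=1).dropna()
                if len(merged) < 3 or merged.iloc[:, 0].std(ddof=0) == 0:
                    row[f"r_{idx}"], row[f"sig_{idx}"] = np.nan, ""
                else:
                    r, p = _pearson_with_p(
                        merged.iloc[:, 0].to_numpy(), merged.iloc[:, 1].to_numpy()
                    )
                    row[f"r_{idx}"] = r
                    row[f"sig_{idx}"] = significance_stars(p)
            rows.append(row)
    if missing:
        raise GrowthDynError(
            f"trait/day combinations absent: {missing}", {"missing": missing}
        )
    return pd.DataFrame(rows)
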