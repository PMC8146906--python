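"""Fuzzy c-means clustering of temporal biomass profiles.

Profiles (one per genotype: the replicate-mean trajectory over the
imaging-day grid) are clustered with the classical fuzzy c-means
alternating optimisation:

    v_k = sum_i u_ik^m x_i / sum_i u_ik^m
    u_ik = 1 / sum_j (||x_i - v_k|| / ||x_i - v_j||)^(2/(m-1))

minimising J = sum_i sum_k u_ik^m ||x_i - v_k||^2.  The number of
clusters is chosen by majority vote over six validity indices
(partition coefficient, modified partition coefficient, partition
entropy, Xie-Beni, Fukuyama-Sugeno, fuzzy silhouette).  Profiles are
clustered on the raw (unstandardised) scale by default, since the
biological groups of interest differ in overall size; pass
``standardize=True`` for shape-based clustering.

Cluster labels are canonicalised by descending mean trajectory level:
cluster 0 ("A") is the larger-biomass group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import GrowthDynError
from .io import TraitTable, genotype_means, wide_matrix

__all__ = [
    "FuzzyCMeans",
    "FuzzyPartition",
    "ValidityReport",
    "select_c_majority",
    "typical_curves",
    "cluster_diff_profile",
    "validity_indices",
    "INDEX_CONVENTIONS",
]


@dataclass
class FuzzyPartition:
    """Result of a fuzzy c-means fit.

    ``membership`` rows sum to 1; ``objective`` is the fuzzy
    within-cluster sum of squares at convergence; ``hard_labels`` is
    the argmax-membership assignment.  ``objective_history`` records
    the per-iteration objective of the winning restart (non-increasing
    by construction of the alternating updates).
    """

    membership: np.ndarray  # n x c
    centers: np.ndarray  # c x T
    objective: float
    m: float
    hard_labels: np.ndarray  # n
    seed: int | None
    restarts: int
    n_iter: int
    objective_history: np.ndarray
    profile_ids: list[str] | None = None
    degenerate_centers: bool = False

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    def recomputed_objective(self, X: np.ndarray) -> float:
        d2 = cdist(X, self.centers, "sqeuclidean")
        return float(np.sum(self.membership**self.m * d2))

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.hard_labels == k)


def _fcm_once(
    X: np.ndarray, c: int, m: float, rng: np.random.Generator,
    tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    n = X.shape[0]
    U = rng.dirichlet(np.ones(c), size=n)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        Um = U**m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, V, "sqeuclidean")
        history.append(float(np.sum(Um * d2)))
        # membership update; exact coincidence with a center -> crisp 1
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        U_new = np.where(np.isfinite(inv), inv, 0.0)
        zero_rows = d2.min(axis=1) == 0.0
        if zero_rows.any():
            U_new[zero_rows] = (d2[zero_rows] == 0.0).astype(float)
        U_new /= U_new.sum(axis=1, keepdims=True)
        shift = float(np.abs(U_new - U).max())
        U = U_new
        if shift < tol:
            break
    Um = U**m
    V = (Um.T @ X) / Um.sum(axis=0)[:, None]
    d2 = cdist(X, V, "sqeuclidean")
    history.append(float(np.sum(Um * d2)))
    return U, V, history, it


class FuzzyCMeans:
    """Fuzzy c-means estimator (best-of-restarts).

    Parameters
    ----------
    n_clusters : int
    m : float
        Fuzzifier, > 1; 2.0 by default (m -> 1 approaches hard k-means).
    restarts : int
        Independent Dirichlet-random membership initialisations; the
        partition with the lowest objective wins.
    tol : float
        Stop when the max absolute membership change drops below this.
    standardize : bool
        Z-score each time column before clustering (shape-based mode).
    """

    def __init__(
        self,
        n_clusters: int,
        m: float = 2.0,
        restarts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 300,
        seed: int | None = None,
        standardize: bool = False,
    ):
        if m <= 1:
            raise GrowthDynError("fuzzifier m must exceed 1", {"m": m})
        if n_clusters < 1:
            raise GrowthDynError("n_clusters must be >= 1")
        self.n_clusters = n_clusters
        self.m = m
        self.restarts = restarts
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.standardize = standardize

    def fit(self, X: np.ndarray | pd.DataFrame) -> FuzzyPartition:
        ids = list(X.index.astype(str)) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise GrowthDynError("profiles contain missing cells; fill or drop upstream")
        n, c = X.shape[0], self.n_clusters
        if n < c:
            raise GrowthDynError(f"need n >= c, got n={n}, c={c}")
        if self.standardize:
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(max(1, self.restarts)):
            U, V, hist, it = _fcm_once(X, c, self.m, rng, self.tol, self.max_iter)
            if best is None or hist[-1] < best[2][-1]:
                best = (U, V, hist, it)
        U, V, hist, it = best
        # canonical order: descending mean center level ("A" = biggest)
        order = np.argsort(-V.mean(axis=1), kind="stable")
        U, V = U[:, order], V[order]
        labels = np.argmax(U, axis=1)
        degenerate = False
        if c > 1:
            dc = cdist(V, V)
            degenerate = bool((dc[np.triu_indices(c, 1)] < 1e-9).any())
            if degenerate:
                warnings.warn(
                    "coincident cluster centers: fewer than c distinct "
                    "centers are supported by the data",
                    stacklevel=2,
                )
        return FuzzyPartition(
            membership=U,
            centers=V,
            objective=hist[-1],
            m=self.m,
            hard_labels=labels,
            seed=self.seed,
            restarts=self.restarts,
            n_iter=it,
            objective_history=np.asarray(hist),
            profile_ids=ids,
            degenerate_centers=degenerate,
        )


# -- validity indices -----------------------------------------------------

#: optimisation direction of each index when voting for c
INDEX_CONVENTIONS = {
    "partition_coefficient": "max",
    "modified_partition_coefficient": "max",
    "partition_entropy": "min",
    "xie_beni": "min",
    "fukuyama_sugeno": "min",
    "fuzzy_silhouette": "max",
}


def _fuzzy_silhouette(X: np.ndarray, part: FuzzyPartition, alpha: float = 1.0) -> float:
    n = X.shape[0]
    labels = part.hard_labels
    D = cdist(X, X)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        a = D[i, own].mean() if own.any() else 0.0
        bs = [
            D[i, labels == k].mean()
            for k in range(part.n_clusters)
            if k != labels[i] and (labels == k).any()
        ]
        if not bs:
            return np.nan
        b = min(bs)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    Usort = np.sort(part.membership, axis=1)
    w = (Usort[:, -1] - Usort[:, -2]) ** alpha
    return float(np.nan) if w.sum() == 0 else float((w * s).sum() / w.sum())


def validity_indices(X: np.ndarray, part: FuzzyPartition) -> dict[str, float]:
    """The six cluster-validity indices for one fitted partition."""
    U, V, m = part.membership, part.centers, part.m
    n, c = U.shape
    pc = float((U**2).sum() / n)
    mpc = 1.0 - (c / (c - 1.0)) * (1.0 - pc) if c > 1 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = float(-(np.where(U > 0, U * np.log(U), 0.0)).sum() / n)
    d2 = cdist(X, V, "sqeuclidean")
    J = float((U**m * d2).sum())
    if c > 1:
        dv2 = cdist(V, V, "sqeuclidean")
        sep = dv2[np.triu_indices(c, 1)].min()
        xb = J / (n * sep) if sep > 0 else np.inf
    else:
        xb = np.nan
    xbar = X.mean(axis=0)
    fs = J - float((U**m).sum(axis=0) @ ((V - xbar) ** 2).sum(axis=1))
    return {
        "partition_coefficient": pc,
        "modified_partition_coefficient": mpc,
        "partition_entropy": pe,
        "xie_beni": xb,
        "fukuyama_sugeno": fs,
        "fuzzy_silhouette": _fuzzy_silhouette(X, part),
    }


@dataclass
class ValidityReport:
    """Per-c validity-index table, one vote per index, and the winner.

    Ties in the vote count break to the smallest c (parsimony).
    """

    table: pd.DataFrame  # rows c, columns indices
    votes: dict[str, int]  # index name -> voted c
    selected_c: int
    partitions: dict[int, FuzzyPartition] = field(default_factory=dict)


def select_c_majority(
    profiles: np.ndarray | pd.DataFrame,
    c_range: range | list[int] = range(2, 7),
    m: float = 2.0,
    seed: int | None = None,
    restarts: int = 20,
    standardize: bool = False,
) -> ValidityReport:
    """Fit fuzzy c-means per candidate c and vote with six indices.

    Candidates yielding a degenerate partition (an empty hard cluster)
    are excluded from the vote with a warning.
    """
    Xarr = np.asarray(profiles, dtype=float)
    n = Xarr.shape[0]
    c_range = [c for c in c_range]
    if any(c < 2 or c > n - 1 for c in c_range):
        raise GrowthDynError(f"c_range must lie within [2, n-1] = [2, {n - 1}]")
    rows, parts = {}, {}
    for c in c_range:
        part = FuzzyCMeans(
            c, m=m, restarts=restarts, seed=seed, standardize=standardize
        ).fit(profiles)
        counts = np.bincount(part.hard_labels, minlength=c)
        if (counts == 0).any():
            warnings.warn(f"c={c}: empty hard cluster, excluded from vote", stacklevel=2)
            continue
        X_for_idx = Xarr
        if standardize:
            sd = Xarr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X_for_idx = (Xarr - Xarr.mean(axis=0)) / sd
        rows[c] = validity_indices(X_for_idx, part)
        parts[c] = part
    if not rows:
        raise GrowthDynError("no non-degenerate partition in c_range")
    table = pd.DataFrame(rows).T.sort_index()
    votes = {}
    for name, conv in INDEX_CONVENTIONS.items():
        col = table[name].dropna()
        if col.empty:
            continue
        votes[name] = int(col.idxmax() if conv == "max" else col.idxmin())
    counts = pd.Series(votes).value_counts()
    top = counts[counts == counts.max()].index
    selected = int(min(top))
    return ValidityReport(table=table, votes=votes, selected_c=selected, partitions=parts)


# -- downstream summaries --------------------------------------------------

def typical_curves(
    partition: FuzzyPartition,
    profiles: pd.DataFrame,
    window: tuple[int, int] = (19, 23),
) -> pd.DataFrame:
    """Per-cluster mean biomass polyline over the peak-to-rebound window.

    Rows are cluster labels (A, B, ...); columns the window days;
    values the mean over the cluster's *hard* members.
    """
    lo, hi = window
    days = [d for d in profiles.columns if lo <= int(d) <= hi]
    missing = set(range(lo, hi + 1)) - set(int(d) for d in profiles.columns)
    if missing:
        raise GrowthDynError(f"window days {sorted(missing)} not on profile grid")
    out = {}
    for k in range(partition.n_clusters):
        idx = partition.members(k)
        if len(idx) == 0:
            raise GrowthDynError(f"cluster {k} has no hard members")
        out[chr(ord("A") + k)] = profiles.iloc[idx][days].mean(axis=0).to_numpy()
    res = pd.DataFrame(out, index=days).T
    res.index.name = "cluster"
    res.columns.name = "dat"
    return res


def cluster_diff_profile(
    partition: FuzzyPartition,
    profiles: pd.DataFrame,
) -> pd.Series:
    """-log10(p) per imaging day for the two-cluster contrast.

    Per day, a two-sample Welch t-test compares genotype means between
    the two hard clusters.  Requires exactly two hard clusters with at
    least two members each.
    """
    labels = partition.hard_labels
    present = np.unique(labels)
    if len(present) != 2:
        raise GrowthDynError(
            f"differential profile needs exactly 2 hard clusters, got {len(present)}"
        )
    ia, ib = (np.flatnonzero(labels == k) for k in present)
    if len(ia) < 2 or len(ib) < 2:
        raise GrowthDynError("each cluster needs >= 2 members for the t-test")
    A = profiles.iloc[ia].to_numpy(dtype=float)
    B = profiles.iloc[ib].to_numpy(dtype=float)
    res = stats.ttest_ind(A, B, axis=0, equal_var=False)
    out = pd.Series(-np.log10(res.pvalue), index=profiles.columns, name="neg_log10_p")
    out.index.name = "dat"
    return out


def cluster_profiles(
    table: TraitTable, trait: str = "EBv", treatment: str = "W"
) -> pd.DataFrame:
    """Genotype x day profile matrix ready for clustering (complete rows only)."""
    mat = wide_matrix(genotype_means(table, trait), treatment)
    return mat.dropna(axis=0)
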