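"""Per-day variance-component decomposition.

Gaussian linear mixed model, fitted separately for each imaging day:

    y_gtr = mu + rep_r (fixed) + G_g + T_t + (GT)_gt + e_gtr

with genotype, treatment and their interaction random.  REML estimates
are obtained by an iterative bounded optimisation of the restricted
likelihood; on a *balanced* layout that likelihood factorises over the
ANOVA strata, so the unconstrained optimum coincides exactly with the
closed-form expected-mean-squares (EMS) estimators — which this module
also exposes as an independent cross-check.  Negative components are
truncated at zero and percentages renormalised to sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import GrowthDynError
from .io import TraitTable

__all__ = [
    "VarianceComponentsModel",
    "VarianceComponentsResults",
    "variance_components_day",
    "variance_components_series",
]

COMPONENTS = ("genotype", "treatment", "genotype:treatment", "residual")


@dataclass
class _Strata:
    """Balanced-ANOVA mean squares and the coefficients linking each
    stratum's expected mean square to the variance components."""

    ms: dict[str, float]
    df: dict[str, float]
    G: int
    T: int
    R: int

    def expected_ms_coefficients(self) -> dict[str, np.ndarray]:
        # order: (sigma2_G, sigma2_T, sigma2_GT, sigma2_e)
        G, T, R = self.G, self.T, self.R
        return {
            "genotype": np.array([T * R, 0.0, R, 1.0]),
            "treatment": np.array([0.0, G * R, R, 1.0]),
            "genotype:treatment": np.array([0.0, 0.0, R, 1.0]),
            "residual": np.array([0.0, 0.0, 0.0, 1.0]),
        }


class VarianceComponentsModel:
    """REML decomposition of one day's observations.

    Parameters
    ----------
    data : DataFrame
        Columns ``genotype``, ``treatment``, ``replicate``, ``value``
        for a single trait at a single day.
    """

    def __init__(self, data: pd.DataFrame):
        need = {"genotype", "treatment", "replicate", "value"}
        if not need <= set(data.columns):
            raise GrowthDynError(f"data must have columns {sorted(need)}")
        df = data.copy()
        self.data = df
        self.G = df["genotype"].nunique()
        self.T = df["treatment"].nunique()
        self.R = df["replicate"].nunique()
        if self.G < 2 or self.T < 2:
            raise GrowthDynError(
                "need >= 2 levels of genotype and treatment",
                {"G": self.G, "T": self.T},
            )
        counts = df.groupby(["genotype", "treatment"]).size()
        self.balanced = (
            len(counts) == self.G * self.T and counts.nunique() == 1
            and counts.iloc[0] == self.R
            and df.groupby(["genotype", "treatment", "replicate"]).size().max() == 1
        )

    @classmethod
    def from_table(cls, table: TraitTable, trait: str, dat: int) -> "VarianceComponentsModel":
        df = table.subset(trait=trait)
        df = df[df["dat"] == int(dat)]
        if df.empty:
            raise GrowthDynError(f"no data for {trait} at DAT {dat}")
        return cls(df)

    # -- balanced ANOVA strata -------------------------------------------

    def _strata(self) -> _Strata:
        df = self.data
        G, T, R = self.G, self.T, self.R
        y = df["value"].to_numpy(float)
        grand = y.mean()
        gm = df.groupby("genotype")["value"].mean()
        tm = df.groupby("treatment")["value"].mean()
        rm = df.groupby("replicate")["value"].mean()
        cm = df.groupby(["genotype", "treatment"])["value"].mean()
        ss_g = T * R * float(((gm - grand) ** 2).sum())
        ss_t = G * R * float(((tm - grand) ** 2).sum())
        ss_r = G * T * float(((rm - grand) ** 2).sum())
        inter = cm - gm.reindex(cm.index.get_level_values(0)).to_numpy() \
            - tm.reindex(cm.index.get_level_values(1)).to_numpy() + grand
        ss_gt = R * float((inter**2).sum())
        ss_tot = float(((y - grand) ** 2).sum())
        ss_e = ss_tot - ss_g - ss_t - ss_r - ss_gt
        n = len(y)
        df_e = n - G * T - R + 1
        return _Strata(
            ms={
                "genotype": ss_g / (G - 1),
                "treatment": ss_t / (T - 1),
                "genotype:treatment": ss_gt / ((G - 1) * (T - 1)),
                "residual": ss_e / df_e,
            },
            df={
                "genotype": G - 1,
                "treatment": T - 1,
                "genotype:treatment": (G - 1) * (T - 1),
                "residual": df_e,
            },
            G=G, T=T, R=R,
        )

    def ems_estimates(self) -> pd.Series:
        """Closed-form expected-mean-squares (ANOVA) estimators.

        May be negative; on balanced data these equal the unconstrained
        REML optimum exactly.
        """
        if not self.balanced:
            raise GrowthDynError("EMS estimators require a balanced layout")
        s = self._strata()
        ms = s.ms
        G, T, R = s.G, s.T, s.R
        sig_e = ms["residual"]
        sig_gt = (ms["genotype:treatment"] - sig_e) / R
        sig_g = (ms["genotype"] - ms["genotype:treatment"]) / (T * R)
        sig_t = (ms["treatment"] - ms["genotype:treatment"]) / (G * R)
        return pd.Series(
            [sig_g, sig_t, sig_gt, sig_e], index=list(COMPONENTS), name="sigma2"
        )

    # -- REML -------------------------------------------------------------

    def _reml_neg_loglik_balanced(self, sigma2: np.ndarray, s: _Strata) -> float:
        coef = s.expected_ms_coefficients()
        nll = 0.0
        for name in COMPONENTS:
            lam = float(coef[name] @ sigma2)
            if lam <= 0:
                return np.inf
            nll += 0.5 * s.df[name] * (np.log(lam) + s.ms[name] / lam)
        return nll

    def fit(self, bounded: bool = True) -> "VarianceComponentsResults":
        """Maximise the restricted likelihood.

        ``bounded=True`` (default) constrains every component to be
        non-negative; ``bounded=False`` returns the unconstrained
        optimum (identical to :meth:`ems_estimates` on balanced data).
        """
        if self.balanced:
            s = self._strata()
            ems = self.ems_estimates().to_numpy()
            if not bounded:
                est, converged = ems.copy(), True
            elif (ems >= 0).all():
                est, converged = ems.copy(), True  # interior optimum
            else:
                # optimise on a unit scale so the answer (and hence the
                # percentage decomposition) is exactly scale-invariant
                scale = float(np.mean(list(s.ms.values()))) or 1.0
                s_unit = _Strata(
                    ms={k: v / scale for k, v in s.ms.items()},
                    df=s.df, G=s.G, T=s.T, R=s.R,
                )
                x0 = np.clip(ems / scale, 1e-8, None)
                res = optimize.minimize(
                    self._reml_neg_loglik_balanced,
                    x0,
                    args=(s_unit,),
                    method="L-BFGS-B",
                    bounds=[(0.0, None)] * 4,
                )
                est, converged = res.x * scale, bool(res.success)
            loglik = -self._reml_neg_loglik_balanced(np.maximum(est, 1e-300), s)
            return VarianceComponentsResults(self, est, converged, loglik, "reml-strata")
        warnings.warn(
            "unbalanced layout: using the general iterative REML", stacklevel=2
        )
        return self._fit_general(bounded)

    def _fit_general(self, bounded: bool) -> "VarianceComponentsResults":
        df = self.data
        y = df["value"].to_numpy(float)
        n = len(y)
        X = pd.get_dummies(df["replicate"].astype(str), drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones(n), X])
        Zs = [
            pd.get_dummies(df["genotype"]).to_numpy(float),
            pd.get_dummies(df["treatment"]).to_numpy(float),
            pd.get_dummies(
                df["genotype"].astype(str) + ":" + df["treatment"].astype(str)
            ).to_numpy(float),
        ]

        def neg_reml(log_s2):
            s2 = np.exp(log_s2)
            V = s2[3] * np.eye(n)
            for s, Z in zip(s2[:3], Zs):
                V += s * (Z @ Z.T)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf
            Vi_y = np.linalg.solve(V, y)
            Vi_X = np.linalg.solve(V, X)
            XtViX = X.T @ Vi_X
            beta = np.linalg.solve(XtViX, X.T @ Vi_y)
            r = y - X @ beta
            Vi_r = np.linalg.solve(V, r)
            logdetV = 2.0 * np.log(np.diag(L)).sum()
            sign, logdetX = np.linalg.slogdet(XtViX)
            return 0.5 * (logdetV + logdetX + r @ Vi_r)

        x0 = np.log(np.full(4, y.var(ddof=1) / 4 + 1e-8))
        res = optimize.minimize(neg_reml, x0, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        est = np.exp(res.x)
        if bounded:
            est = np.maximum(est, 0.0)
        return VarianceComponentsResults(
            self, est, bool(res.success), -res.fun, "reml-general"
        )


@dataclass
class VarianceComponentsResults:
    model: VarianceComponentsModel
    _sigma2: np.ndarray
    converged: bool
    loglik: float
    method: str

    @property
    def variances(self) -> pd.Series:
        """Truncated (non-negative) variance components."""
        return pd.Series(np.maximum(self._sigma2, 0.0), index=list(COMPONENTS),
                         name="sigma2")

    @property
    def variances_raw(self) -> pd.Series:
        """Untruncated estimates (may be negative if fitted unbounded)."""
        return pd.Series(self._sigma2, index=list(COMPONENTS), name="sigma2_raw")

    @property
    def percentages(self) -> pd.Series:
        v = self.variances
        total = v.sum()
        if total <= 0:
            raise GrowthDynError("total variance is zero")
        out = 100.0 * v / total
        return out.rename("percent")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sigma2": self.variances, "percent": self.percentages}
        )


def variance_components_day(
    table: TraitTable, trait: str, dat: int
) -> VarianceComponentsResults:
    """Fit the per-day mixed model and return the REML decomposition."""
    return VarianceComponentsModel.from_table(table, trait, dat).fit()


def variance_components_series(
    table: TraitTable, trait: str = "EBv"
) -> pd.DataFrame:
    """Percent variance explained per component for every imaging day."""
    rows = {}
    for dat in table.grid:
        try:
            rows[dat] = variance_components_day(table, trait, dat).percentages
        except GrowthDynError:
            continue
    out = pd.DataFrame(rows).T
    out.index.name = "dat"
    return out
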