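"""Repeated-measures covariance-structure fitting and BIC selection.

Given a subjects x time response matrix with a saturated mean (a free
mean per time point), five within-subject covariance models are fitted
by maximum likelihood and compared by BIC:

* ``UN``       uniform (compound symmetry): sigma^2 [(1-rho) I + rho J], 2 params
* ``POWER``    continuous-time AR(1): sigma^2 rho^|ti-tj|, 2 params
* ``HETPOWER`` heterogeneous power: sigma_i sigma_j rho^|ti-tj|, T+1 params
* ``ANTE``     first-order antedependence: sigma_i sigma_j prod rho_k, 2T-1 params
* ``US``       unstructured SPD, T(T+1)/2 params

Time distances are *actual day distances*, so an irregular grid (e.g. a
missing imaging day) enters POWER/HETPOWER correlations as a gap of 2.
UN, ANTE and US maximum-likelihood fits have closed forms; POWER and
HETPOWER are optimised over unconstrained transforms (log sigma,
tanh-link rho) so every proposal is positive definite by construction.

BIC = -2 logL + n_params * ln(n_subjects); the saturated mean is common
to all structures and not counted.  Note the naming convention: "UN"
here is *uniform* (compound symmetry), not unstructured — that is "US".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, GrowthDynError

__all__ = [
    "RepeatedMeasuresModel",
    "CovarianceFit",
    "fit_covariance_structure",
    "select_structure_bic",
    "STRUCTURES",
]

STRUCTURES = ("UN", "POWER", "HETPOWER", "ANTE", "US")


def n_params_for(structure: str, T: int) -> int:
    return {
        "UN": 2,
        "POWER": 2,
        "HETPOWER": T + 1,
        "ANTE": 2 * T - 1,
        "US": T * (T + 1) // 2,
    }[structure]


def _gaussian_loglik(S: np.ndarray, Sigma: np.ndarray, n: int) -> float:
    """logL of n subjects with sample covariance S (divisor n) under a
    zero-mean (mean-profiled-out) Gaussian with covariance Sigma."""
    T = S.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    tr = float(np.trace(np.linalg.solve(Sigma, S)))
    return -0.5 * n * (T * np.log(2.0 * np.pi) + logdet + tr)


@dataclass
class CovarianceFit:
    """One fitted covariance structure.

    ``params`` is a named parameter Series; ``sigma`` the implied T x T
    covariance matrix; ``bic`` uses the number of subjects as sample
    size (the common mixed-model convention).
    """

    structure: str
    params: pd.Series
    sigma: np.ndarray
    loglik: float
    n_params: int
    n_subjects: int
    times: np.ndarray
    converged: bool = True
    status: str = "ok"

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_subjects)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "structure": self.structure,
                "loglik": self.loglik,
                "n_params": self.n_params,
                "bic": self.bic,
                "converged": self.converged,
            }
        )


class RepeatedMeasuresModel:
    """Saturated-mean Gaussian model for subjects x time data.

    Parameters
    ----------
    Y : array or DataFrame, shape (n_subjects, T)
        One row per subject (genotype-mean profiles by default in the
        pipeline; per-plant profiles are equally valid).
    times : sequence of numbers
        The imaging days; used as real distances by POWER/HETPOWER.
    """

    def __init__(self, Y: np.ndarray | pd.DataFrame, times=None):
        if isinstance(Y, pd.DataFrame):
            if times is None:
                times = [float(c) for c in Y.columns]
            Y = Y.to_numpy(dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise GrowthDynError("Y must be n_subjects x T with T >= 2")
        if np.isnan(Y).any():
            raise GrowthDynError("Y contains missing values")
        if times is None:
            times = np.arange(Y.shape[1], dtype=float)
        times = np.asarray(times, dtype=float)
        if len(times) != Y.shape[1] or np.any(np.diff(times) <= 0):
            raise GrowthDynError("times must be strictly increasing, length T")
        self.Y = Y
        self.times = times
        self.n, self.T = Y.shape
        Yc = Y - Y.mean(axis=0, keepdims=True)
        #: ML sample covariance (divisor n), the saturated-model estimate
        self.S = (Yc.T @ Yc) / self.n
        self._lag = np.abs(times[:, None] - times[None, :])

    def fit(self, structure: str) -> CovarianceFit:
        structure = structure.upper()
        if structure not in STRUCTURES:
            raise GrowthDynError(f"unknown structure {structure!r}")
        k = n_params_for(structure, self.T)
        if self.n <= k:
            warnings.warn(
                f"{structure}: {k} covariance parameters for only "
                f"{self.n} subjects; estimates will be unstable",
                stacklevel=2,
            )
        return getattr(self, f"_fit_{structure.lower()}")()

    def fit_all(self, structures=STRUCTURES) -> list[CovarianceFit]:
        fits = []
        for s in structures:
            try:
                fits.append(self.fit(s))
            except ConvergenceError as e:  # keep going, record nothing
                warnings.warn(f"{s}: {e}", stacklevel=2)
        return fits

    # -- closed forms -----------------------------------------------------

    def _fit_us(self) -> CovarianceFit:
        Sigma = self.S.copy()
        names = [
            f"cov[{i},{j}]" for i in range(self.T) for j in range(i, self.T)
        ]
        vals = [Sigma[i, j] for i in range(self.T) for j in range(i, self.T)]
        return CovarianceFit(
            "US",
            pd.Series(vals, index=names),
            Sigma,
            _gaussian_loglik(self.S, Sigma, self.n),
            n_params_for("US", self.T),
            self.n,
            self.times,
        )

    def _fit_un(self) -> CovarianceFit:
        T, S = self.T, self.S
        one = np.ones(T)
        t1 = float(one @ S @ one) / T  # mean-direction stratum
        t2 = float(np.trace(S)) - t1
        lam1 = max(t1, 1e-12)
        lam2 = max(t2 / (T - 1), 1e-12)
        sigma2 = (lam1 + (T - 1) * lam2) / T
        rho = (lam1 - lam2) / (lam1 + (T - 1) * lam2)
        Sigma = sigma2 * ((1 - rho) * np.eye(T) + rho * np.ones((T, T)))
        return CovarianceFit(
            "UN",
            pd.Series({"sigma2": sigma2, "rho": rho}),
            Sigma,
            _gaussian_loglik(S, Sigma, self.n),
            2,
            self.n,
            self.times,
        )

    def _fit_ante(self) -> CovarianceFit:
        # decomposable model on cliques {t, t+1}: ML matches the sample
        # variances and adjacent-pair correlations
        S, T = self.S, self.T
        sd = np.sqrt(np.diag(S))
        if (sd == 0).any():
            raise ConvergenceError("zero variance at a time point")
        rho = np.array(
            [S[k, k + 1] / (sd[k] * sd[k + 1]) for k in range(T - 1)]
        )
        rho = np.clip(rho, -0.999999, 0.999999)
        Sigma = self._ante_sigma(sd, rho)
        names = [f"sd[{i}]" for i in range(T)] + [f"rho[{k}]" for k in range(T - 1)]
        return CovarianceFit(
            "ANTE",
            pd.Series(np.concatenate([sd, rho]), index=names),
            Sigma,
            _gaussian_loglik(S, Sigma, self.n),
            n_params_for("ANTE", T),
            self.n,
            self.times,
        )

    @staticmethod
    def _ante_sigma(sd: np.ndarray, rho: np.ndarray) -> np.ndarray:
        T = len(sd)
        R = np.eye(T)
        for i in range(T):
            prod = 1.0
            for j in range(i + 1, T):
                prod *= rho[j - 1]
                R[i, j] = R[j, i] = prod
        return np.outer(sd, sd) * R

    # -- numeric fits -----------------------------------------------------

    def _power_sigma(self, sd: np.ndarray, rho: float) -> np.ndarray:
        return np.outer(sd, sd) * rho ** self._lag

    def _fit_power(self) -> CovarianceFit:
        S = self.S

        def unpack(x):
            return np.exp(x[0] / 2.0), np.tanh(x[1])

        def nll(x):
            sd, rho = unpack(x)
            Sigma = self._power_sigma(np.full(self.T, sd), rho)
            ll = _gaussian_loglik(S, Sigma, self.n)
            return -ll if np.isfinite(ll) else 1e300

        r0 = self._init_rho()
        x0 = np.array([np.log(np.trace(S) / self.T), np.arctanh(np.clip(r0, -0.99, 0.99))])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        sd, rho = unpack(res.x)
        Sigma = self._power_sigma(np.full(self.T, sd), rho)
        return CovarianceFit(
            "POWER",
            pd.Series({"sigma2": sd * sd, "rho": rho}),
            Sigma,
            -res.fun,
            2,
            self.n,
            self.times,
            converged=bool(res.success),
            status=res.message if not res.success else "ok",
        )

    def _fit_hetpower(self) -> CovarianceFit:
        S, T = self.S, self.T

        def unpack(x):
            return np.exp(x[:T]), np.tanh(x[T])

        def nll(x):
            sd, rho = unpack(x)
            ll = _gaussian_loglik(S, self._power_sigma(sd, rho), self.n)
            return -ll if np.isfinite(ll) else 1e300

        r0 = self._init_rho()
        x0 = np.concatenate(
            [0.5 * np.log(np.clip(np.diag(S), 1e-12, None)),
             [np.arctanh(np.clip(r0, -0.99, 0.99))]]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        sd, rho = unpack(res.x)
        Sigma = self._power_sigma(sd, rho)
        names = [f"sd[{i}]" for i in range(T)] + ["rho"]
        return CovarianceFit(
            "HETPOWER",
            pd.Series(np.concatenate([sd, [rho]]), index=names),
            Sigma,
            -res.fun,
            T + 1,
            self.n,
            self.times,
            converged=bool(res.success),
            status=res.message if not res.success else "ok",
        )

    def _init_rho(self) -> float:
        """Average adjacent-lag correlation scaled to per-unit-day."""
        sd = np.sqrt(np.clip(np.diag(self.S), 1e-12, None))
        rs = []
        for k in range(self.T - 1):
            gap = self.times[k + 1] - self.times[k]
            r = self.S[k, k + 1] / (sd[k] * sd[k + 1])
            if r > 0:
                rs.append(r ** (1.0 / gap))
        return float(np.mean(rs)) if rs else 0.5


def fit_covariance_structure(
    Y: np.ndarray | pd.DataFrame, times=None, structure: str = "US"
) -> CovarianceFit:
    """Functional wrapper: fit one structure to a response matrix."""
    return RepeatedMeasuresModel(Y, times).fit(structure)


def select_structure_bic(
    fits: list[CovarianceFit],
) -> tuple[CovarianceFit, pd.DataFrame]:
    """Pick the converged fit with the lowest BIC; return the full table."""
    ok = [f for f in fits if f.converged]
    if len(ok) < 1:
        raise ConvergenceError("no converged covariance fit")
    table = pd.DataFrame([f.summary() for f in fits]).set_index("structure")
    table = table.sort_values("bic")
    best = min(ok, key=lambda f: f.bic)
    return best, table
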