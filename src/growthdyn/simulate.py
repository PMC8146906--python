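"""Synthetic replicate-level growth trajectories.

Emulates a greenhouse phenotyping experiment: 20 genotypes x 4
treatments (control C, low nitrogen N, water stress W, combined NW) x 8
replicates imaged on 33 days (DAT 2..35, day 30 missing).  Biomass
(estimated biovolume, EBv, arbitrary voxel units) follows

    EBv_g(t) = K_g / (1 + exp(-r_g (t - t0_g))) * N_g(t) * S_g(t) * eps

where the logistic term is genotype-specific growth, ``N_g`` a mild
late-ramping nitrogen penalty (1 in C and W), ``S_g`` a water-stress
factor (1 in C and N) and ``eps`` multiplicative lognormal noise.

The stress factor declines as a power-law ramp from 1 at stress onset
(DAT 9) to ``1 - delta_g`` at maximum stress (DAT 22), then relaxes
exponentially toward 1 at rate ``gamma_g`` after rewatering:

    S_g(t) = 1 - delta_g * ((t - 9) / 13)^p                9 <= t <= 22
    S_g(t) = 1 - delta_g * exp(-gamma_g (t - 22))          t > 22

The exponent ``p`` (decline_power, default 9) concentrates the damage
in the final days before maximum stress: wilting under progressive soil
drying accelerates as soil water approaches the critical level, which
is what produces deep 1-3-day biomass declines immediately after peak
growth rather than a gradual season-long drag.

Genotypes fall into two latent groups: group A (12 genotypes) is
larger-bodied with a deeper stress dip; group B (8) is smaller, faster
growing relative to its size, with a shallower dip.  Group means are
calibrated so that the cohort-mean W/C biomass ratio at DAT 22 is about
0.49 (a ~51 % reduction), group A peaks at DAT 20 and group B at
DAT 21 under water stress, and both trough at DAT 22.

Secondary traits (height PHg, surface coverage SCov, solidity Sol,
colour ratios Y2G/B2G, fluorescence FI) are deterministic links to EBv
and to instantaneous stress intensity ``1 - S_g(t)``, plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DEFAULT_GRID, TREATMENTS, COLUMNS, TraitTable

__all__ = [
    "GroupParams",
    "Dispersion",
    "SimulationConfig",
    "simulate_experiment",
    "ground_truth",
    "stress_factor",
    "water_applied_phase",
]


@dataclass(frozen=True)
class GroupParams:
    """Latent-group means of the per-genotype growth/stress parameters.

    K : logistic asymptote (voxels, arbitrary units)
    r : logistic rate (day^-1)
    t0 : logistic inflection day (DAT)
    delta : fractional biomass dip at maximum stress, in [0, 1)
    gamma : post-rewatering recovery rate (day^-1)
    """

    K: float
    r: float
    t0: float
    delta: float
    gamma: float


@dataclass(frozen=True)
class Dispersion:
    """Genotype-level spread around the group means.

    Multiplicative lognormal CVs for K/gamma, additive normal SDs for
    r/t0/delta (delta clipped to [0, 0.95)).
    """

    K_cv: float = 0.10
    r_sd: float = 0.02
    t0_sd: float = 0.20
    delta_sd: float = 0.03
    gamma_cv: float = 0.20


# Group A: 12 large-bodied genotypes, deeper dip, stress peak at DAT 20.
# Group B: 8 smaller, relatively faster-growing genotypes, shallower
# dip, stress peak at DAT 21.  Calibrated analytically (see module
# docstring); cohort-mean delta = (12*0.52 + 8*0.48)/20 = 0.504, so the
# mean W/C biomass ratio at the trough is ~0.48-0.50.
_DEFAULT_GROUPS = {
    "A": GroupParams(K=1.2e5, r=0.25, t0=20.0, delta=0.52, gamma=0.02),
    "B": GroupParams(K=0.6e5, r=0.35, t0=21.0, delta=0.48, gamma=0.02),
}

_ALL_TRAITS = ("EBv", "PHg", "SCov", "Sol", "Y2G", "B2G", "FI")


@dataclass(frozen=True)
class SimulationConfig:
    n_genotypes: int = 20
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 8
    dat_grid: tuple[int, ...] = DEFAULT_GRID
    group_sizes: dict = field(default_factory=lambda: {"A": 12, "B": 8})
    group_params: dict = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    dispersion: Dispersion = Dispersion()
    stress_onset_dat: int = 9
    trough_dat: int = 22
    nitrogen_onset_dat: int = 15
    nitrogen_max_penalty: float = 0.08
    nw_synergy: float = 0.04
    decline_power: float = 9.0
    noise_cv: float = 0.08
    #: grams of water applied per day, per treatment (WUE denominator);
    #: irrigation volumes are not experiment-derived, just plausible.
    water_applied: dict = field(
        default_factory=lambda: {"C": 250.0, "N": 250.0, "W": 120.0, "NW": 120.0}
    )
    traits: tuple[str, ...] = _ALL_TRAITS
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_genotypes < 1:
            bad.append("n_genotypes")
        if self.n_replicates < 1:
            bad.append("n_replicates")
        if sum(self.group_sizes.values()) != self.n_genotypes:
            bad.append("group_sizes")
        for name, gp in self.group_params.items():
            if not (0 <= gp.delta < 1):
                bad.append(f"group_params[{name}].delta")
            if gp.r <= 0 or gp.gamma <= 0 or gp.K <= 0:
                bad.append(f"group_params[{name}]")
        if self.noise_cv < 0:
            bad.append("noise_cv")
        if not set(self.treatments) <= set(TREATMENTS):
            bad.append("treatments")
        if bad:
            raise ValidationError(
                "invalid simulation config fields: " + ", ".join(bad),
                {"fields": bad},
            )

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def stress_factor(
    t: np.ndarray,
    delta: float,
    gamma: float,
    onset: int = 9,
    trough: int = 22,
    power: float = 9.0,
) -> np.ndarray:
    """Water-stress multiplier S(t) on biomass: 1 before onset, power-law
    decline to ``1 - delta`` at the trough day, exponential relaxation
    after.  ``power`` > 1 concentrates the dip near the trough."""
    t = np.asarray(t, dtype=float)
    s = np.ones_like(t)
    span = trough - onset
    dip = (t > onset) & (t <= trough)
    s[dip] = 1.0 - delta * ((t[dip] - onset) / span) ** power
    rec = t > trough
    s[rec] = 1.0 - delta * np.exp(-gamma * (t[rec] - trough))
    return s


def _nitrogen_factor(t: np.ndarray, onset: int, max_penalty: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    ramp = np.clip((t - onset) / (35.0 - onset), 0.0, 1.0)
    return 1.0 - max_penalty * ramp


def _draw_genotype_params(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    gid = 0
    disp = config.dispersion
    for group in sorted(config.group_sizes):
        gp = config.group_params[group]
        for _ in range(config.group_sizes[group]):
            gid += 1
            K = gp.K * np.exp(rng.normal(0.0, disp.K_cv))
            r = max(gp.r + rng.normal(0.0, disp.r_sd), 0.05)
            t0 = gp.t0 + rng.normal(0.0, disp.t0_sd)
            delta = float(np.clip(gp.delta + rng.normal(0.0, disp.delta_sd), 0.0, 0.95))
            gamma = max(gp.gamma * np.exp(rng.normal(0.0, disp.gamma_cv)), 1e-3)
            rows.append(
                {
                    "genotype": f"G{gid:02d}",
                    "group": group,
                    "K": float(K),
                    "r": float(r),
                    "t0": float(t0),
                    "delta": delta,
                    "gamma": float(gamma),
                }
            )
    return pd.DataFrame(rows)


def ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-genotype latent parameters exactly as used by
    :func:`simulate_experiment` under the same config (same seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _draw_genotype_params(config, rng)


def expected_ebv(
    params: pd.Series | dict, t: np.ndarray, treatment: str, config: SimulationConfig
) -> np.ndarray:
    """Noise-free EBv trajectory for one genotype under one treatment
    (the generator's closed form; used as an oracle in tests)."""
    t = np.asarray(t, dtype=float)
    L = params["K"] / (1.0 + np.exp(-params["r"] * (t - params["t0"])))
    out = L
    if treatment in ("N", "NW"):
        out = out * _nitrogen_factor(
            t, config.nitrogen_onset_dat, config.nitrogen_max_penalty
        )
    if treatment in ("W", "NW"):
        out = out * stress_factor(
            t,
            params["delta"],
            params["gamma"],
            config.stress_onset_dat,
            config.trough_dat,
            config.decline_power,
        )
    if treatment == "NW":
        ramp = np.clip((t - config.trough_dat) / (35.0 - config.trough_dat), 0.0, 1.0)
        out = out * (1.0 - config.nw_synergy * ramp)
    return out


def simulate_experiment(config: SimulationConfig | None = None) -> TraitTable:
    """Generate the full long-format trait table for one experiment.

    Under defaults this yields 20 x 4 x 8 x 33 = 21,120 EBv records plus
    the same count for each secondary trait requested.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _draw_genotype_params(config, rng)
    t = np.asarray(config.dat_grid, dtype=float)
    T = len(t)
    R = config.n_replicates

    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal

    def noise(shape):
        if config.noise_cv == 0:
            return np.ones(shape)
        return np.exp(rng.normal(mu, sigma, size=shape))

    K_med = float(params["K"].median())
    frames = []
    for _, p in params.iterrows():
        # smallness in [0, 1]: drives the post-trough coverage boost
        small = float(np.clip(2.0 * (1.0 - p["K"] / K_med), 0.0, 1.0))
        for treat in config.treatments:
            ebv_det = expected_ebv(p, t, treat, config)
            if treat in ("W", "NW"):
                intensity = 1.0 - stress_factor(
                    t, p["delta"], p["gamma"],
                    config.stress_onset_dat, config.trough_dat,
                    config.decline_power,
                )
            else:
                intensity = np.zeros(T)
            ebv = ebv_det[None, :] * noise((R, T))
            cols = {"EBv": ebv}
            if "PHg" in config.traits:
                cols["PHg"] = 2.0 * ebv ** (1.0 / 3.0) * noise((R, T))
            post = (t > config.trough_dat).astype(float)
            boost = 1.0 + 0.15 * small * post * intensity
            if "SCov" in config.traits:
                half = 0.4 * p["K"]
                cols["SCov"] = (
                    900.0 * (ebv / (ebv + half)) * boost[None, :] * noise((R, T))
                )
            if "Sol" in config.traits:
                half = 0.4 * p["K"]
                cols["Sol"] = np.clip(
                    (0.30 + 0.45 * ebv_det[None, :] / (ebv_det[None, :] + half))
                    * boost[None, :]
                    + rng.normal(0.0, 0.01 * config.noise_cv / 0.08 if config.noise_cv else 0.0, (R, T)),
                    1e-6, 1.0,
                )
            if "Y2G" in config.traits:
                cols["Y2G"] = np.clip(
                    0.20 + 0.50 * intensity[None, :]
                    + rng.normal(0.0, 0.02 * config.noise_cv / 0.08 if config.noise_cv else 0.0, (R, T)),
                    1e-6, None,
                )
            if "B2G" in config.traits:
                cols["B2G"] = np.clip(
                    0.10 + 0.30 * intensity[None, :]
                    + rng.normal(0.0, 0.015 * config.noise_cv / 0.08 if config.noise_cv else 0.0, (R, T)),
                    1e-6, None,
                )
            if "FI" in config.traits:
                cols["FI"] = 100.0 * (1.0 + 0.8 * intensity[None, :]) * noise((R, T))
            reps = np.repeat(np.arange(1, R + 1), T)
            dats = np.tile(config.dat_grid, R)
            for trait, arr in cols.items():
                frames.append(
                    pd.DataFrame(
                        {
                            "genotype": p["genotype"],
                            "treatment": treat,
                            "replicate": reps,
                            "dat": dats,
                            "trait": trait,
                            "value": arr.ravel(),
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True).loc[:, list(COLUMNS)]
    return TraitTable(df, grid=config.dat_grid)


def water_applied_phase(
    config: SimulationConfig, treatment: str, start_dat: int, end_dat: int
) -> float:
    """Grams of water applied to one plant between two days (exclusive
    of the start day, inclusive of the end), under the constant per-day
    schedule."""
    per_day = config.water_applied[treatment]
    return float(per_day * (end_dat - start_dat))
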