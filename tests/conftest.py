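import numpy as np
import pandas as pd
import pytest

import growthdyn as gd
from growthdyn.io import COLUMNS
from growthdyn.simulate import Dispersion


def make_table(records, grid=None):
    df = pd.DataFrame(records, columns=list(COLUMNS))
    return gd.TraitTable(df, grid=grid or gd.DEFAULT_GRID)


@pytest.fixture
def toy_table():
    """1 genotype, 2 treatments, 3 days, 2 replicates of EBv."""
    rows = []
    for treat, base in (("C", 10.0), ("W", 8.0)):
        for rep, off in ((1, 0.0), (2, 2.0)):
            for i, dat in enumerate((2, 3, 4)):
                rows.append(("G01", treat, rep, dat, "EBv", base + off + i))
    return make_table(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic experiment at seed 1."""
    cfg = gd.SimulationConfig(seed=1)
    return cfg, gd.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free cohort (genotype parameters still dispersed)."""
    cfg = gd.SimulationConfig(seed=1, noise_cv=0.0, traits=("EBv",))
    return cfg, gd.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def crisp_cohort():
    """Zero-dispersion, zero-noise cohort: genotypes equal their group
    means exactly; used for closed-form group-level checks."""
    cfg = gd.SimulationConfig(
        seed=1, noise_cv=0.0,
        dispersion=Dispersion(0.0, 0.0, 0.0, 0.0, 0.0),
        traits=("EBv",),
    )
    return cfg, gd.simulate_experiment(cfg)


def adjusted_rand(a, b):
    """Adjusted Rand index between two label vectors (exact combinatorial
    formula; independent of any clustering code)."""
    a, b = np.asarray(a), np.asarray(b)
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def c2(x):
        return x * (x - 1) / 2.0

    sij = c2(ct).sum()
    si = c2(ct.sum(axis=1)).sum()
    sj = c2(ct.sum(axis=0)).sum()
    n = c2(ct.sum())
    exp = si * sj / n
    mx = (si + sj) / 2.0
    return 1.0 if mx == exp else (sij - exp) / (mx - exp)
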