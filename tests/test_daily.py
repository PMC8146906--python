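import numpy as np
import pandas as pd
import pytest
from scipy import stats

import growthdyn as gd
from growthdyn.daily import (
    onset_detection,
    onset_for_contrast,
    pearson_critical_value,
    per_day_treatment_test,
)
from growthdyn.errors import GrowthDynError

from conftest import make_table


def one_day_table(rng, shifts, G=8, R=4, dat=10, sigma=1.0):
    """One imaging day, one treatment shift per group."""
    rows = []
    for treat, shift in shifts.items():
        for g in range(G):
            for r in range(R):
                rows.append(
                    (f"g{g:02d}", treat, r + 1, dat, "EBv",
                     50.0 + shift + rng.normal(0, sigma))
                )
    return make_table(rows)


class TestPerDayTest:
    def test_identical_vectors_p_one(self):
        rows = []
        vals = [1.0, 2.0, 3.0, 4.0]
        for treat in ("C", "W"):
            for r, v in enumerate(vals):
                rows.append(("g1", treat, r + 1, 5, "EBv", v + 10))
        res = per_day_treatment_test(make_table(rows), "EBv", 5)
        assert res.loc["C-W", "p_adj"] == pytest.approx(1.0, abs=1e-6)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        t = one_day_table(rng, {"C": 0.0, "W": -5.0, "N": 0.0, "NW": -5.0})
        res = per_day_treatment_test(t, "EBv", 10)
        assert res.loc["C-W", "p_adj"] < 0.001
        assert res.loc["C-N", "p_adj"] > 0.05

    def test_replicate_effect_absorbed(self):
        # a replicate (bench) effect should not inflate the treatment test
        rng = np.random.default_rng(1)
        rows = []
        for treat in ("C", "W"):
            for g in range(6):
                for r in range(4):
                    rows.append(
                        (f"g{g}", treat, r + 1, 10, "EBv",
                         50.0 + 10.0 * r + rng.normal(0, 1.0))
                    )
        t = make_table(rows)
        res = per_day_treatment_test(t, "EBv", 10)
        # residual df reflect the fitted replicate effects: n - 1 - 1 - 3
        assert res.loc["C-W", "df"] == 48 - 5
        assert res.loc["C-W", "p_adj"] > 0.01

    def test_singular_design_rejected(self):
        rows = [("g1", "C", 1, 5, "EBv", 1.0), ("g1", "W", 1, 5, "EBv", 2.0)]
        with pytest.raises(GrowthDynError):
            per_day_treatment_test(make_table(rows), "EBv", 5)

    def test_null_familywise_error_quick(self):
        # ~5% of null datasets show any significant pair (small version
        # of the calibration study in the acceptance suite)
        rng = np.random.default_rng(2)
        k, hits, sims = 4, 0, 100
        for _ in range(sims):
            t = one_day_table(rng, {"C": 0, "N": 0, "W": 0, "NW": 0}, G=5, R=3)
            res = per_day_treatment_test(t, "EBv", 10)
            hits += (res["p_adj"] <= 0.05).any()
        assert hits / sims <= 0.12


class TestOnsetDetection:
    def test_no_significance_null_onset(self):
        rep = onset_detection(pd.Series([0.2, 0.3, 0.4], index=[2, 3, 4]))
        assert rep.onset_dat is None and rep.runs == []

    def test_hand_traced_runs_with_persistence(self):
        p = pd.Series([0.2, 0.2, 0.01, 0.03, 0.2, 0.01],
                      index=[2, 3, 4, 5, 6, 7])
        rep = onset_detection(p, persistence=2)
        assert rep.onset_dat == 4
        assert rep.runs == [(4, 5), (7, 7)]

    def test_persistence_one_takes_first_hit(self):
        p = pd.Series([0.2, 0.04, 0.2, 0.01], index=[2, 3, 4, 5])
        rep = onset_detection(p, persistence=1)
        assert rep.onset_dat == 3
        assert rep.runs == [(3, 3), (5, 5)]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        p = pd.Series(rng.uniform(0, 0.2, 12), index=range(2, 14))
        onset_strict = onset_detection(p, alpha=0.01).onset_dat
        onset_loose = onset_detection(p, alpha=0.10).onset_dat
        if onset_strict is not None:
            assert onset_loose is not None and onset_loose <= onset_strict

    def test_engineered_divergence_recovered(self):
        # W drops below C from DAT 15 with a 3-sigma effect
        rng = np.random.default_rng(4)
        grid = tuple(range(10, 21))
        hits = 0
        for _ in range(20):
            rows = []
            for dat in grid:
                eff = -3.0 if dat >= 15 else 0.0
                for treat, shift in (("C", 0.0), ("W", eff)):
                    for g in range(6):
                        for r in range(3):
                            rows.append(
                                (f"g{g}", treat, r + 1, dat, "EBv",
                                 50 + shift + rng.normal(0, 1.0))
                            )
            t = make_table(rows, grid=grid)
            # persistence 2 suppresses isolated pre-divergence false hits
            rep = onset_for_contrast(t, "EBv", "W", "C", persistence=2)
            hits += rep.onset_dat is not None and abs(rep.onset_dat - 15) <= 1
        assert hits >= 18

    def test_cohort_w_onset_before_n_onset(self, default_cohort):
        # water stress bites earlier than the mild late nitrogen penalty
        _, table = default_cohort
        w = onset_for_contrast(table, "EBv", "W", "C")
        n = onset_for_contrast(table, "EBv", "N", "C")
        assert w.onset_dat is not None
        assert w.onset_dat > 9  # not before stress initiation
        if n.onset_dat is not None:
            assert w.onset_dat < n.onset_dat


class TestCorrelationSeries:
    def test_self_correlation_is_one(self, default_cohort):
        _, table = default_cohort
        cs = gd.correlation_series(table, "EBv", "EBv", "C")
        assert np.allclose(cs.r, 1.0)
        assert cs.significant.all()

    def test_critical_value_closed_form(self):
        n = 20
        t975 = stats.t.ppf(0.975, n - 2)
        expect = t975 / np.sqrt(n - 2 + t975**2)
        assert pearson_critical_value(20) == pytest.approx(expect, abs=1e-12)
        # inverting back: t = r sqrt(n-2)/sqrt(1-r^2) hits the quantile
        r = pearson_critical_value(20)
        assert r * np.sqrt(18) / np.sqrt(1 - r * r) == pytest.approx(t975)

    def test_null_trait_calibration(self):
        rng = np.random.default_rng(5)
        n, hits, total = 20, 0, 0
        crit = pearson_critical_value(n)
        for _ in range(40):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) >= crit
            total += 1
        assert 0.0 <= hits / total <= 0.15

    def test_height_tracks_biomass(self, default_cohort):
        # PHg is a cube-root link of EBv: strongly positive r throughout
        _, table = default_cohort
        cs = gd.correlation_series(table, "PHg", "EBv", "C")
        assert (cs.r > 0.5).all()
        assert cs.significant.all()
        assert (cs.n == 20).all()

    def test_flags_match_critical_value(self, default_cohort):
        _, table = default_cohort
        cs = gd.correlation_series(table, "Y2G", "EBv", "W")
        expect = cs.r.abs() >= cs.critical_value
        assert (cs.significant == expect).all()
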