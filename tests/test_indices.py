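import numpy as np
import pandas as pd
import pytest

import growthdyn as gd
from growthdyn.errors import GrowthDynError, UndefinedScoreError
from growthdyn.indices import capability_scores, capability_table, significance_stars
from growthdyn.io import GrowthCurve
from growthdyn.simulate import Dispersion, GroupParams


ANCHOR_DATS = (2, 9, 22, 23, 35)


def curve(means, treatment, genotype="g1", dats=ANCHOR_DATS):
    return GrowthCurve(genotype, treatment, tuple(dats), tuple(means),
                       (1,) * len(dats))


class TestCapabilityScores:
    def test_identity_curves_give_ones(self):
        c = curve([1.0, 2.0, 10.0, 11.0, 30.0], "C")
        w = curve([1.0, 2.0, 10.0, 11.0, 30.0], "W")
        s = capability_scores(w, c)
        assert (s.dto, s.drc, s.dad) == (1.0, 1.0, 1.0)

    def test_half_increments_give_half(self):
        ctrl = [1.0, 2.0, 10.0, 11.0, 30.0]
        c = curve(ctrl, "C")
        # stress increments exactly half of control's in every window
        base = 5.0
        w_vals = [base]
        for a, b in zip(ctrl, ctrl[1:]):
            base += (b - a) / 2.0
            w_vals.append(base)
        w = curve(w_vals, "W")
        s = capability_scores(w, c)
        assert s.dto == pytest.approx(0.5)
        assert s.drc == pytest.approx(0.5)
        assert s.dad == pytest.approx(0.5)

    def test_undefined_window_named(self):
        c = curve([1.0, 10.0, 5.0, 11.0, 30.0], "C")  # control declines 9->22
        w = curve([1.0, 2.0, 3.0, 4.0, 5.0], "W")
        with pytest.raises(UndefinedScoreError) as exc:
            capability_scores(w, c)
        assert exc.value.reason["index"] == "dto"

    def test_rescaling_invariance(self):
        c = curve([1.0, 2.0, 10.0, 11.0, 30.0], "C")
        w = curve([1.0, 1.5, 6.0, 7.0, 20.0], "W")
        s1 = capability_scores(w, c)
        k = 13.7
        s2 = capability_scores(
            curve([k * v for v in w.means], "W"),
            curve([k * v for v in c.means], "C"),
        )
        for f in ("dto", "drc", "dad"):
            assert getattr(s1, f) == pytest.approx(getattr(s2, f))

    def test_dad_between_dto_drc_for_proportional_control(self):
        # control increments proportional across windows -> DAD is a
        # weighted average of DTO and DRC
        c = curve([1.0, 10.0, 30.0, 31.0, 50.0], "C")
        w = curve([1.0, 5.0, 13.0, 14.0, 30.0], "W")
        s = capability_scores(w, c)
        assert min(s.dto, s.drc) <= s.dad <= max(s.dto, s.drc)

    def test_dto_tracks_generator_tolerance_noisefree(self, noisefree_cohort):
        cfg, table = noisefree_cohort
        gt = gd.ground_truth(cfg).set_index("genotype")
        scores = capability_table(table, "W")
        merged = scores.join(gt)
        rho = merged["dto"].rank().corr(merged["delta"].rank(), method="spearman")
        assert rho <= -0.9


class TestCapabilityCorrelations:
    def test_perfect_correlation_when_equal(self):
        scores = pd.DataFrame(
            {"dto": [0.2, 0.5, 0.9, 0.4], "drc": [0.3, 0.6, 0.8, 0.5],
             "dad": [0.3, 0.6, 0.8, 0.5]},
            index=[f"g{i}" for i in range(4)],
        )
        r, p = gd.capability_correlations(scores)
        assert r.loc["drc", "dad"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)
        pd.testing.assert_frame_equal(r, r.T)

    def test_constant_column_flagged(self):
        scores = pd.DataFrame(
            {"dto": [0.5, 0.5, 0.5], "drc": [0.3, 0.6, 0.8],
             "dad": [0.3, 0.5, 0.9]},
            index=list("abc"),
        )
        r, _ = gd.capability_correlations(scores)
        assert np.isnan(r.loc["dto", "drc"])

    def test_too_few_genotypes(self):
        scores = pd.DataFrame({"dto": [1.0], "drc": [1.0], "dad": [1.0]})
        with pytest.raises(GrowthDynError):
            gd.capability_correlations(scores)

    def test_recovery_driven_dad_correlates_with_drc(self):
        # construction: recovery rate varies, dip depth fixed -> DAD
        # variation is driven by recovery, not tolerance
        cfg = gd.SimulationConfig(
            seed=9, noise_cv=0.0, traits=("EBv",),
            group_params={
                "A": GroupParams(1.2e5, 0.25, 20.0, 0.50, 0.05),
                "B": GroupParams(1.2e5, 0.25, 20.0, 0.50, 0.05),
            },
            # tiny growth jitter so DTO is not exactly constant
            dispersion=Dispersion(0.0, 0.005, 0.05, 0.0, 0.6),
        )
        table = gd.simulate_experiment(cfg)
        scores = capability_table(table, "W")
        r, _ = gd.capability_correlations(scores)
        assert abs(r.loc["dad", "drc"]) > abs(r.loc["dad", "dto"])


class TestTraitCapabilityTable:
    def test_self_trait_correlates_perfectly(self, default_cohort):
        _, table = default_cohort
        scores = capability_table(table, "W")
        # inject a trait equal to dto at both anchor days
        rows = []
        for g, dto in scores["dto"].items():
            for dat in (22, 35):
                rows.append((g, "W", 1, dat, "DTOproxy", dto))
        df = pd.concat(
            [table.data,
             pd.DataFrame(rows, columns=table.data.columns)],
            ignore_index=True,
        )
        t2 = gd.TraitTable(df, grid=table.grid)
        res = gd.trait_capability_table(t2, scores, "W", traits=["DTOproxy"])
        assert np.allclose(res["r_dto"], 1.0)
        assert (res["sig_dto"] == "***").all()

    def test_ebv_at_max_stress_positively_tracks_dto(self):
        # single-group cohort with dispersed dip depth: tolerance
        # preserves biomass at maximum stress, so EBv(22) under W is
        # positively, significantly correlated with DTO.  (In a
        # two-group cohort this direction is confounded by plant size.)
        cfg = gd.SimulationConfig(
            seed=4,
            group_sizes={"A": 20},
            group_params={"A": GroupParams(1.0e5, 0.25, 20.0, 0.50, 0.02)},
            dispersion=Dispersion(0.05, 0.02, 0.2, 0.10, 0.2),
            traits=("EBv",),
        )
        table = gd.simulate_experiment(cfg)
        scores = capability_table(table, "W")
        res = gd.trait_capability_table(table, scores, "W", traits=["EBv"])
        r22 = res[res["dat"] == 22]["r_dto"].iloc[0]
        assert r22 > 0
        assert res[res["dat"] == 22]["sig_dto"].iloc[0] != ""

    def test_null_trait_rarely_significant(self):
        # independent noise trait, n=20: |r| below the p=0.05 critical
        # value in >= 90% of simulations
        rng = np.random.default_rng(12)
        n, hits, sims = 20, 0, 100
        from growthdyn.indices import _pearson_with_p

        for _ in range(sims):
            x, y = rng.normal(size=n), rng.normal(size=n)
            _, p = _pearson_with_p(x, y)
            hits += p <= 0.05
        assert hits <= 0.10 * sims

    def test_missing_trait_day_listed(self, default_cohort):
        _, table = default_cohort
        scores = capability_table(table, "W")
        with pytest.raises(GrowthDynError) as exc:
            gd.trait_capability_table(table, scores, "W", traits=["ghost"])
        assert ("ghost", 22) in exc.value.reason["missing"]


def test_significance_star_convention():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.2) == ""
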