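import numpy as np
import pandas as pd
import pytest

import growthdyn as gd
from growthdyn.cluster import (
    FuzzyCMeans,
    cluster_diff_profile,
    cluster_profiles,
    select_c_majority,
    typical_curves,
    validity_indices,
)
from growthdyn.errors import GrowthDynError

from conftest import adjusted_rand


def two_clouds(rng, n_per=15, T=8, sep=20.0, spread=1.0):
    a = rng.normal(0.0, spread, (n_per, T))
    b = rng.normal(sep, spread, (n_per, T))
    X = np.vstack([a, b])
    return X, np.repeat([0, 1], n_per)


class TestFCM:
    def test_c1_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        part = FuzzyCMeans(1, seed=0, restarts=1).fit(X)
        np.testing.assert_allclose(part.centers[0], X.mean(axis=0), atol=1e-10)
        assert part.objective == pytest.approx(
            float(((X - X.mean(axis=0)) ** 2).sum()), rel=1e-10
        )

    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(1)
        X, truth = two_clouds(rng, sep=30.0, spread=1.0)
        part = FuzzyCMeans(2, seed=1).fit(X)
        assert adjusted_rand(part.hard_labels, truth) == 1.0
        assert part.membership.max(axis=1).min() > 0.95

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        part = FuzzyCMeans(3, seed=2).fit(X)
        np.testing.assert_allclose(part.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_nonincreasing_and_recomputable(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.normal(size=(25, 7)) * rng.uniform(0.5, 3)
            part = FuzzyCMeans(3, seed=int(rng.integers(1e6)), restarts=3).fit(X)
            assert np.all(np.diff(part.objective_history) <= 1e-9)
            assert part.objective == pytest.approx(
                part.recomputed_objective(X), abs=1e-8 * (1 + part.objective)
            )

    def test_profile_on_center_gets_crisp_membership(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0], [10.0, 10.0]])
        part = FuzzyCMeans(2, seed=0, restarts=5).fit(X)
        # duplicated points coincide with their center exactly
        crisp = part.membership.max(axis=1)
        assert np.all(crisp > 1.0 - 1e-9)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 5))
        a = FuzzyCMeans(2, seed=42).fit(X)
        b = FuzzyCMeans(2, seed=42).fit(X)
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.hard_labels, b.hard_labels)

    def test_canonical_label_order_by_level(self):
        rng = np.random.default_rng(5)
        X, _ = two_clouds(rng, sep=15.0)
        part = FuzzyCMeans(2, seed=5).fit(X)
        # cluster 0 ("A") is the higher-level trajectory group
        assert part.centers[0].mean() > part.centers[1].mean()

    def test_n_less_than_c_rejected(self):
        with pytest.raises(GrowthDynError):
            FuzzyCMeans(5).fit(np.zeros((3, 4)))

    def test_invalid_fuzzifier(self):
        with pytest.raises(GrowthDynError):
            FuzzyCMeans(2, m=1.0)


class TestSelectC:
    def test_two_separated_groups_pick_two(self):
        rng = np.random.default_rng(6)
        X, _ = two_clouds(rng, sep=25.0)
        report = select_c_majority(X, seed=6, restarts=5)
        assert report.selected_c == 2
        votes_for_2 = sum(1 for v in report.votes.values() if v == 2)
        assert votes_for_2 >= 4

    def test_partition_coefficient_decreases_with_c(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))  # one spherical cloud
        report = select_c_majority(X, c_range=range(2, 6), seed=7, restarts=5)
        pc = report.table["partition_coefficient"]
        assert (pc.diff().dropna() < 0).all()

    def test_paper_like_cohort_selects_two(self, default_cohort):
        _, table = default_cohort
        profiles = cluster_profiles(table, "EBv", "W")
        report = select_c_majority(profiles, seed=1, restarts=10)
        assert report.selected_c == 2

    def test_c_range_bounds(self):
        with pytest.raises(GrowthDynError):
            select_c_majority(np.zeros((5, 3)), c_range=range(2, 7))


class TestTypicalCurves:
    def test_single_member_identity(self):
        prof = pd.DataFrame(
            [[10.0, 11.0, 12.0, 9.0, 10.0]], index=["g1"],
            columns=[19, 20, 21, 22, 23],
        )
        part = FuzzyCMeans(1, seed=0, restarts=1).fit(prof)
        tc = typical_curves(part, prof)
        np.testing.assert_allclose(tc.loc["A"], prof.iloc[0])

    def test_two_member_mean(self):
        prof = pd.DataFrame(
            [[10, 10, 10, 8, 9], [12, 12, 12, 10, 11]],
            index=["g1", "g2"], columns=[19, 20, 21, 22, 23], dtype=float,
        )
        part = FuzzyCMeans(1, seed=0, restarts=1).fit(prof)
        tc = typical_curves(part, prof)
        np.testing.assert_allclose(tc.loc["A"], [11, 11, 11, 9, 10])

    def test_group_peak_days_match_design(self, crisp_cohort):
        # designed group curves: A peaks DAT 20, B at DAT 21, trough 22
        _, table = crisp_cohort
        profiles = cluster_profiles(table, "EBv", "W")
        part = FuzzyCMeans(2, seed=0).fit(profiles)
        tc = typical_curves(part, profiles)
        assert int(tc.columns[np.argmax(tc.loc["A"])]) == 20
        assert int(tc.columns[np.argmax(tc.loc["B"])]) == 21
        assert int(tc.columns[np.argmin(tc.loc["A"])]) == 22

    def test_window_off_grid(self):
        prof = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=[19, 20])
        part = FuzzyCMeans(1, seed=0, restarts=1).fit(prof)
        with pytest.raises(GrowthDynError):
            typical_curves(part, prof)


class TestDiffProfile:
    def _make(self, rng, offset_sd=0.0, n=8, T=6):
        a = rng.normal(0.0, 1.0, (n, T))
        b = rng.normal(offset_sd, 1.0, (n, T))
        prof = pd.DataFrame(np.vstack([a, b]), columns=range(2, 2 + T))
        labels = np.repeat([0, 1], n)
        part = FuzzyCMeans(2, seed=0, restarts=3).fit(prof)
        return prof, part, labels

    def test_strong_offset_everywhere_significant(self):
        rng = np.random.default_rng(8)
        prof, part, truth = self._make(rng, offset_sd=10.0)
        assert adjusted_rand(part.hard_labels, truth) == 1.0
        d = cluster_diff_profile(part, prof)
        assert (d > 3).all()

    def test_null_rarely_strong(self):
        rng = np.random.default_rng(9)
        hits = total = 0
        for _ in range(30):
            a = rng.normal(0.0, 1.0, (8, 6))
            b = rng.normal(0.0, 1.0, (8, 6))
            prof = pd.DataFrame(np.vstack([a, b]), columns=range(6))
            part = FuzzyCMeans(1, seed=0, restarts=1).fit(prof)
            # impose an arbitrary (truth-blind) split to get a null test
            part.hard_labels = np.repeat([0, 1], 8)
            part.centers = np.vstack([part.centers, part.centers])
            d = cluster_diff_profile(part, prof)
            hits += int((d >= 1.3010299956639813).sum())  # -log10(0.05)
            total += len(d)
        assert hits / total < 0.10

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(10)
        prof, part, _ = self._make(rng, offset_sd=5.0)
        d1 = cluster_diff_profile(part, prof)
        order = np.concatenate([
            rng.permutation(np.flatnonzero(part.hard_labels == 0)),
            rng.permutation(np.flatnonzero(part.hard_labels == 1)),
        ])
        prof2 = prof.iloc[order].copy()
        part2 = FuzzyCMeans(2, seed=0, restarts=3).fit(prof2)
        d2 = cluster_diff_profile(part2, prof2)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_small_cluster_rejected(self):
        prof = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
        part = FuzzyCMeans(2, seed=0, restarts=3).fit(prof)
        with pytest.raises(GrowthDynError):
            cluster_diff_profile(part, prof)


class TestValidityIndices:
    def test_indices_finite_and_conventional(self):
        rng = np.random.default_rng(11)
        X, _ = two_clouds(rng, sep=10.0)
        part = FuzzyCMeans(2, seed=11).fit(X)
        idx = validity_indices(X, part)
        assert 0.5 <= idx["partition_coefficient"] <= 1.0
        assert idx["partition_entropy"] >= 0.0
        assert idx["xie_beni"] > 0.0
        assert -1.0 <= idx["fuzzy_silhouette"] <= 1.0


class TestGroupRecovery:
    def test_default_cohort_ari(self, default_cohort):
        cfg, table = default_cohort
        truth = gd.ground_truth(cfg).set_index("genotype")["group"]
        profiles = cluster_profiles(table, "EBv", "W")
        part = FuzzyCMeans(2, seed=3).fit(profiles)
        labels = pd.Series(part.hard_labels, index=profiles.index)
        assert adjusted_rand(labels, truth[profiles.index].map({"A": 0, "B": 1})) >= 0.8
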