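"""Disparity metrics, bootstrap CIs and the two permutation tests."""

import numpy as np
import pytest

from elytron import (
    bootstrap_disparity,
    pcoa,
    permutation_test,
    product_of_variances,
    select_axes,
    subsampled_permutation_test,
    sum_of_variances,
)
from elytron.disparity import DECISION_NONE, DECISION_OLDER
from elytron.ordination import OrdinationResult

from test_ordination import dm_from_points


def _fake_pcoa(variances):
    v = np.asarray(variances, dtype=float)
    return OrdinationResult(
        labels=[f"t{i}" for i in range(3)], scores=np.zeros((3, v.size)),
        method="PCoA", eigenvalues=v, axis_variance=v / v.sum(),
    )


def _fake_nmds(k=3):
    return OrdinationResult(
        labels=[f"t{i}" for i in range(5)], scores=np.zeros((5, k)),
        method="NMDS", stress=0.1,
    )


class TestSelectAxes:
    def test_prefix_reaching_ninety_percent(self):
        sel = select_axes(_fake_pcoa([0.5, 0.3, 0.15, 0.05]), "cumulative_90")
        assert sel.indices.tolist() == [0, 1, 2]
        assert sel.cumulative_variance == pytest.approx(0.95)

    def test_single_dominant_axis(self):
        sel = select_axes(_fake_pcoa([1.0]), "cumulative_90")
        assert sel.indices.tolist() == [0]

    def test_exact_boundary_is_included(self):
        sel = select_axes(_fake_pcoa([0.9, 0.1]), "cumulative_90")
        assert sel.indices.tolist() == [0]

    def test_nmds_takes_all_axes(self):
        sel = select_axes(_fake_nmds(k=3), "all_axes")
        assert sel.indices.tolist() == [0, 1, 2]

    def test_cumulative_rule_rejected_for_nmds(self):
        with pytest.raises(ValueError, match="PCoA"):
            select_axes(_fake_nmds(), "cumulative_90")


class TestVarianceMetrics:
    def test_sov_hand_value_single_axis(self):
        assert sum_of_variances(np.array([[-1.0], [0.0], [1.0]])) == pytest.approx(1.0)

    def test_sov_adds_across_axes(self):
        rng = np.random.default_rng(0)
        a = rng.normal(scale=1.0, size=100)
        b = rng.normal(scale=2.0, size=100)
        scores = np.column_stack([a, b])
        assert sum_of_variances(scores) == pytest.approx(
            np.var(a, ddof=1) + np.var(b, ddof=1)
        )

    def test_identical_taxa_have_zero_disparity(self):
        scores = np.ones((4, 3))
        assert sum_of_variances(scores) == 0.0
        assert product_of_variances(scores) == 0.0

    def test_pov_is_geometric_mean_of_variances(self):
        scores = np.array([[0.0, 0.0], [2.0, 4.0]])  # variances 2 and 8
        assert product_of_variances(scores) == pytest.approx(4.0)

    def test_pov_single_axis_identity(self):
        x = np.array([[0.0], [1.0], [5.0]])
        assert product_of_variances(x) == pytest.approx(np.var(x, ddof=1))

    def test_degenerate_axis_zeroes_pov(self):
        scores = np.column_stack([np.arange(4.0), np.ones(4)])
        assert product_of_variances(scores) == 0.0

    def test_amgm_bound_on_random_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.normal(size=(rng.integers(2, 30), rng.integers(1, 6)))
            n_axes = scores.shape[1]
            assert product_of_variances(scores) <= (
                sum_of_variances(scores) / n_axes + 1e-12
            )

    def test_sov_over_all_pcoa_axes_equals_total_variance(self):
        """Trace identity: sum of axis variances = variance of the
        embedded configuration."""
        rng = np.random.default_rng(2)
        d = dm_from_points(rng.normal(size=(25, 5)))
        res = pcoa(d, correction="none")
        total = res.scores.var(axis=0, ddof=1).sum()
        assert sum_of_variances(res.scores) == pytest.approx(total, rel=1e-8)
        assert sum_of_variances(res.scores) == pytest.approx(
            res.eigenvalues.sum() / (res.scores.shape[0] - 1), rel=1e-8
        )

    def test_sov_invariant_under_rotation(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(30, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert sum_of_variances(scores @ Q) == pytest.approx(
            sum_of_variances(scores), rel=1e-10
        )

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            sum_of_variances(np.zeros((1, 3)))


class TestBootstrap:
    def test_two_identical_taxa_bootstrap_to_zero(self):
        est = bootstrap_disparity(np.ones((2, 3)), metric="sov", reps=100, seed=0)
        assert (est.bootstrap_distribution == 0).all()
        assert est.ci_low == est.ci_high == 0

    def test_distribution_length_and_determinism(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(20, 3))
        a = bootstrap_disparity(scores, reps=500, seed=9)
        b = bootstrap_disparity(scores, reps=500, seed=9)
        assert a.bootstrap_distribution.shape == (500,)
        np.testing.assert_array_equal(a.bootstrap_distribution,
                                      b.bootstrap_distribution)
        assert a.ci_low <= a.value <= a.ci_high

    def test_ci_brackets_point_estimate_on_normal_scores(self):
        """Coverage check: the percentile CI contains the full-sample
        estimate in >= 94% of 200 seeded normal datasets at n=50."""
        rng = np.random.default_rng(5)
        hits = 0
        for trial in range(200):
            scores = rng.normal(size=(50, 3))
            est = bootstrap_disparity(scores, metric="sov", reps=300, seed=trial)
            hits += est.ci_low <= est.value <= est.ci_high
        assert hits / 200 >= 0.94


class TestPermutationTest:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(25, 3))
        res = permutation_test(scores, scores.copy(), reps=5000, seed=1)
        assert res.observed_T == 0.0
        assert res.proportion == pytest.approx(0.5, abs=0.05)
        assert res.decision == DECISION_NONE

    def test_tenfold_scale_detected_as_older_larger(self):
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(1, 101):
            young = rng.normal(size=(30, 3))
            old = young * 10
            res = permutation_test(old, young, metric="sov", reps=499, seed=seed)
            hits += res.decision == DECISION_OLDER
        assert hits >= 99

    def test_reversal_flips_statistic_and_proportion(self):
        rng = np.random.default_rng(8)
        old = rng.normal(scale=2.0, size=(20, 3))
        young = rng.normal(size=(22, 3))
        fwd = permutation_test(old, young, reps=2000, seed=3)
        rev = permutation_test(young, old, reps=2000, seed=3)
        assert rev.observed_T == pytest.approx(-fwd.observed_T)
        assert rev.proportion == pytest.approx(1 - fwd.proportion, abs=0.03)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(12, 2))
        r1 = permutation_test(a, b, reps=500, seed=5)
        r2 = permutation_test(a, b, reps=500, seed=5)
        assert r1.proportion == r2.proportion

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test(np.zeros((1, 2)), np.zeros((5, 2)))


class TestSubsampledPermutationTest:
    def test_equal_sizes_fall_back_to_plain(self, caplog):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        with caplog.at_level("INFO"):
            res = subsampled_permutation_test(a, b, reps=500, seed=0)
        assert "plain" in res.test

    def test_size_imbalanced_exchangeable_groups_not_significant(self):
        """Triplicated copies of the same cloud differ only in n; the
        size-corrected test must not call a difference."""
        rng = np.random.default_rng(11)
        young = rng.normal(size=(20, 3))
        old = np.vstack([young, young, young])
        res = subsampled_permutation_test(old, young, reps=4000, seed=2)
        assert res.decision == DECISION_NONE
        assert 0.1 < res.proportion < 0.9

    def test_scale_difference_detected_despite_imbalance(self):
        rng = np.random.default_rng(12)
        hits = 0
        for seed in range(1, 101):
            young = rng.normal(size=(20, 3))
            old = rng.normal(scale=10.0, size=(100, 3))
            res = subsampled_permutation_test(old, young, metric="sov",
                                              reps=2000, seed=seed)
            hits += res.decision == DECISION_OLDER
        assert hits >= 99

    def test_replication_count_recorded(self):
        rng = np.random.default_rng(13)
        res = subsampled_permutation_test(
            rng.normal(size=(30, 2)), rng.normal(size=(8, 2)), reps=10000, seed=1
        )
        assert res.replications == 10000
        assert res.test == "subsampled"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=(18, 3)), rng.normal(size=(7, 3))
        r1 = subsampled_permutation_test(a, b, reps=1000, seed=4)
        r2 = subsampled_permutation_test(a, b, reps=1000, seed=4)
        assert r1.proportion == r2.proportion
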