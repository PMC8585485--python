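"""PCoA, Cailliez correction and NMDS against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa as skbio_pcoa

from elytron import (
    SyntheticSpec,
    cailliez_constant,
    goodness_of_fit,
    mord_distance,
    nmds,
    pcoa,
    simulate_character_matrix,
)
from elytron.distances import DistanceMatrix
from elytron.ordination import (
    EIG_REL_TOL,
    _kruskal_descent,
    _monotone_fit,
    trim_missing_pairs,
)


def dm_from_points(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    D = squareform(pdist(X))
    n = len(X)
    return DistanceMatrix(
        labels=[f"p{i}" for i in range(n)], d=D,
        comparable=np.full((n, n), X.shape[1]), metric_tag="MORD",
    )


def dm_from_square(D):
    n = D.shape[0]
    return DistanceMatrix(
        labels=[f"p{i}" for i in range(n)], d=np.asarray(D, dtype=float),
        comparable=np.full((n, n), 1), metric_tag="MORD",
    )


@pytest.fixture(scope="module")
def mord60():
    """Seeded 60-taxon synthetic MORD matrix (five epoch groups)."""
    m, _ = simulate_character_matrix(
        SyntheticSpec(group_sizes=(7, 16, 16, 6, 15),
                      dispersion=(0.08, 0.35, 0.35, 0.08, 0.2), seed=0)
    )
    dm, _ = trim_missing_pairs(mord_distance(m))
    return dm


class TestCailliez:
    def test_planar_points_need_no_correction(self):
        rng = np.random.default_rng(0)
        assert cailliez_constant(dm_from_points(rng.normal(size=(6, 2)))) == 0.0

    def test_collinear_points_need_no_correction(self):
        """d = [[0,1,2],[1,0,1],[2,1,0]] embeds on a line, so c = 0."""
        assert cailliez_constant(dm_from_square(
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]])
        )) == 0.0

    def test_corrected_matrix_has_no_negative_eigenvalues(self, mord60):
        c = cailliez_constant(mord60)
        assert c > 0
        D = mord60.d + c
        np.fill_diagonal(D, 0.0)
        n = D.shape[0]
        J = np.eye(n) - 1 / n
        ev = np.linalg.eigvalsh(-0.5 * J @ D**2 @ J)
        assert ev.min() >= -EIG_REL_TOL * ev.max()

    def test_constant_is_minimal(self, mord60):
        """Adding any smaller constant leaves a negative eigenvalue."""
        c = cailliez_constant(mord60)
        D = mord60.d + 0.9 * c
        np.fill_diagonal(D, 0.0)
        n = D.shape[0]
        J = np.eye(n) - 1 / n
        ev = np.linalg.eigvalsh(-0.5 * J @ D**2 @ J)
        assert ev.min() < -EIG_REL_TOL * ev.max()

    def test_frozen_value_verified_against_reference_implementation(self):
        """c for a seeded matrix; value agrees with R ape::pcoa's Cailliez
        note (0.633162473805524) to 1e-12."""
        m, _ = simulate_character_matrix(
            SyntheticSpec(group_sizes=(6, 6), group_names=("A", "B"),
                          dispersion=(0.2, 0.4), n_characters=12,
                          missing_rate=0.25, seed=3)
        )
        c = cailliez_constant(mord_distance(m))
        assert c == pytest.approx(0.633162473805524, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cailliez_constant(dm_from_square(D))


class TestPcoa:
    def test_line_points_recover_one_axis_and_distances(self):
        d = dm_from_points([0.0, 3.0, 4.0, 5.0])
        res = pcoa(d, correction="none")
        strong = res.eigenvalues > 1e-8 * res.eigenvalues.max()
        assert strong.sum() == 1
        got = squareform(pdist(res.scores))
        np.testing.assert_allclose(got, d.d, atol=1e-8)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        d = dm_from_points(X)
        res = pcoa(d, correction="cailliez")
        assert res.correction_constant == 0.0
        np.testing.assert_allclose(squareform(pdist(res.scores)), d.d, rtol=1e-8,
                                   atol=1e-10)

    def test_axis_variances_sum_to_one_and_scores_centered(self, mord60):
        res = pcoa(mord60)
        assert res.axis_variance.sum() == pytest.approx(1.0)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-8
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_all_zero_distances_give_no_axes(self):
        res = pcoa(dm_from_square(np.zeros((4, 4))), correction="none")
        assert res.n_axes == 0

    def test_matches_scikit_bio_eigenvalues(self, mord60):
        """Independent PCoA oracle: same positive spectrum on the
        Cailliez-corrected matrix."""
        c = cailliez_constant(mord60)
        D = mord60.d + c
        np.fill_diagonal(D, 0.0)
        ref = skbio_pcoa(SkbioDM(D, ids=mord60.labels), method="eigh",
                         number_of_dimensions=0)
        res = pcoa(mord60)
        ref_pos = np.sort(ref.eigvals.values[ref.eigvals.values > 1e-8])[::-1]
        k = min(len(ref_pos), len(res.eigenvalues))
        np.testing.assert_allclose(res.eigenvalues[:k], ref_pos[:k], rtol=1e-6)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            pcoa(dm_from_points([0.0, 1.0]))


class TestNmds:
    def test_euclidean_input_reaches_near_zero_stress(self):
        rng = np.random.default_rng(0)
        d = dm_from_points(rng.normal(size=(20, 3)))
        res = nmds(d, k=3, restarts=5, seed=1)
        assert res.stress < 0.01
        assert res.nonmetric_fit > 0.99

    def test_same_seed_reproduces_scores(self, mord60):
        a = nmds(mord60, k=3, restarts=3, seed=7)
        b = nmds(mord60, k=3, restarts=3, seed=7)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.stress == b.stress

    def test_diagnostics_are_consistent(self, mord60):
        res = nmds(mord60, k=3, restarts=5, seed=2)
        assert 0 <= res.stress <= 1
        assert res.nonmetric_fit == pytest.approx(1 - res.stress**2)
        nonmetric, linear = goodness_of_fit(res, mord60)
        assert nonmetric == pytest.approx(res.nonmetric_fit)
        assert 0 <= linear <= 1

    def test_accepted_stress_trace_is_monotone(self, mord60):
        rng = np.random.default_rng(3)
        delta = squareform(mord60.d, checks=False)
        order = np.argsort(delta, kind="stable")
        X0 = rng.normal(size=(mord60.n, 3))
        _, _, trace = _kruskal_descent(order, X0, max_iter=100, tol=1e-6)
        assert len(trace) > 1
        assert (np.diff(trace) <= 0).all()

    def test_stress_competitive_with_sklearn(self, mord60):
        """Independent optimizer oracle: our best stress-1 is at least as
        good as sklearn's nonmetric MDS (small slack for restart luck)."""
        import warnings
        from sklearn.manifold import MDS

        ours = nmds(mord60, k=3, restarts=10, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MDS(n_components=3, metric=False, dissimilarity="precomputed",
                      n_init=4, random_state=0, normalized_stress=True)
            ref.fit(mord60.d)
        assert ours.stress <= ref.stress_ + 0.02

    def test_stress_reported_for_sixty_taxon_morphospace(self, mord60):
        """The 3-D embedding of the 60-taxon mock reports its stress and
        fits with the run (binary MCAR data embeds worse than real
        matrices; the absolute level is characterized in the docs)."""
        res = nmds(mord60, k=3, restarts=10, seed=0)
        assert res.stress < 0.3
        assert res.nonmetric_fit > 0.9
        assert res.seed == 0

    def test_missing_pair_matrix_rejected_until_trimmed(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        dm = dm_from_square(D)
        with pytest.raises(ValueError, match="missing"):
            nmds(dm, k=2, restarts=1, seed=0)
        trimmed, dropped = trim_missing_pairs(dm)
        assert len(dropped) == 1
        assert not np.isnan(trimmed.d).any()

    def test_k_below_two_rejected(self, mord60):
        with pytest.raises(ValueError, match="k"):
            nmds(mord60, k=1, seed=0)


def test_monotone_fit_is_isotonic_in_dissimilarity_order():
    rng = np.random.default_rng(4)
    delta = rng.random(45)
    dist = delta + rng.normal(scale=0.1, size=45)
    order = np.argsort(delta, kind="stable")
    fitted = _monotone_fit(dist, order)
    assert (np.diff(fitted[order]) >= -1e-12).all()
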