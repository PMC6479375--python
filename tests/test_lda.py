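"""Fisher LDA: scatter identities, eigen-solution optimality, projection."""

import numpy as np
import pytest

from delda.data import FeatureColumn, FeatureTable
from delda.lda import LDAModel, fisher_objective, fit_lda, scatter_matrices, transform


def _table(X, y):
    X = np.asarray(X, dtype=float)
    meta = [FeatureColumn(f"f{j}", "-", "de") for j in range(X.shape[1])]
    return FeatureTable(values=X, labels=np.asarray(y), feature_meta=meta, provenance="t")


SIX_POINTS = _table(
    [(0, 0), (0, 1), (2, 0), (2, 1), (4, 0), (4, 1)], [0, 0, 1, 1, 2, 2]
)
# hand-summed outer products for the six-point set
SW_HAND = np.array([[0.0, 0.0], [0.0, 1.5]])
SB_HAND = np.array([[16.0, 0.0], [0.0, 0.0]])


def _random_classes(rng, n_per=40, n_dim=2, spread=1.0):
    means = rng.normal(0, 4, size=(3, n_dim))
    X = np.vstack([m + spread * rng.standard_normal((n_per, n_dim)) for m in means])
    y = np.repeat([0, 1, 2], n_per)
    return _table(X, y)


class TestScatterMatrices:
    def test_six_point_hand_oracle(self):
        Sw, Sb, St = scatter_matrices(SIX_POINTS)
        np.testing.assert_allclose(Sw, SW_HAND, atol=1e-12)
        np.testing.assert_allclose(Sb, SB_HAND, atol=1e-12)
        np.testing.assert_allclose(St, SW_HAND + SB_HAND, atol=1e-12)

    def test_one_sample_per_class_zero_within(self):
        Sw, _, _ = scatter_matrices(_table([(1, 2), (3, 4), (5, 6)], [0, 1, 2]))
        np.testing.assert_allclose(Sw, 0.0, atol=1e-12)

    def test_all_identical_points(self):
        Sw, Sb, St = scatter_matrices(_table([(2, 2)] * 6, [0, 0, 1, 1, 2, 2]))
        np.testing.assert_allclose(Sw, 0.0, atol=1e-12)
        np.testing.assert_allclose(Sb, 0.0, atol=1e-12)

    def test_total_scatter_decomposition_random(self, rng):
        for _ in range(20):
            n, p = int(rng.integers(9, 60)), int(rng.integers(2, 40))
            X = rng.normal(size=(n, p)) * rng.uniform(0.1, 10)
            y = rng.integers(0, 3, size=n)
            if np.unique(y).size < 2:
                continue
            Sw, Sb, St = scatter_matrices(_table(X, y))
            np.testing.assert_allclose(St, Sw + Sb, rtol=1e-8, atol=1e-8 * np.abs(St).max())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            scatter_matrices(_table([(1, 2), (3, 4)], [0, 0]))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            scatter_matrices(_table(np.zeros((0, 2)), np.zeros(0, dtype=int)))


def _grid_best_direction(Sw_eff, Sb, step_deg=1.0):
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    best = -np.inf
    for th in thetas:
        w = np.array([np.cos(th), np.sin(th)])
        best = max(best, (w @ Sb @ w) / (w @ Sw_eff @ w))
    return best


class TestFitLda:
    def test_two_separated_classes_recover_mean_axis(self, rng):
        X = np.vstack(
            [
                np.array([-5.0, 0.0]) + rng.standard_normal((200, 2)),
                np.array([5.0, 0.0]) + rng.standard_normal((200, 2)),
            ]
        )
        y = np.repeat([0, 1], 200)
        model = fit_lda(_table(X, y), d=1)
        angle = np.degrees(np.arccos(abs(model.projection[0, 0])))
        assert angle <= 5.0

    def test_eigen_beats_one_degree_grid(self, rng):
        for _ in range(5):
            table = _random_classes(rng)
            model = fit_lda(table, d=1, shrinkage=0.0)
            Sw, Sb, _ = scatter_matrices(table)
            w = model.projection[:, 0]
            ours = (w @ Sb @ w) / (w @ Sw @ w)
            assert ours >= _grid_best_direction(Sw, Sb) - 1e-6

    def test_six_point_leading_direction_beats_grid(self):
        # the leading direction must beat every 1-degree grid direction on
        # the (regularized) Fisher quotient; with collinear class means the
        # optimum is the mean axis (x) and the second direction carries no
        # between-class scatter
        Sw, Sb, _ = scatter_matrices(SIX_POINTS)
        n = Sw.shape[0]
        gamma = 1e-6
        Sw_reg = Sw + gamma * (np.trace(Sw) / n) * np.eye(n)
        model = fit_lda(SIX_POINTS, d=2, shrinkage=gamma)
        w1 = model.projection[:, 0]
        ours = (w1 @ Sb @ w1) / (w1 @ Sw_reg @ w1)
        assert ours >= _grid_best_direction(Sw_reg, Sb) - 1e-6
        np.testing.assert_allclose(np.abs(w1), [1.0, 0.0], atol=1e-8)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-8)

    def test_projection_diagonalizes_both_scatters(self, rng):
        # simultaneous diagonalization: distinct eigen-directions are
        # orthogonal under both Sw and Sb (the sense in which each Fisher
        # quotient is maximized subject to the previous directions)
        table = _random_classes(rng, n_per=50, n_dim=4)
        model = fit_lda(table, d=2, shrinkage=0.0)
        Sw, Sb, _ = scatter_matrices(table)
        w1, w2 = model.projection.T
        scale_w = np.abs(Sw).max()
        scale_b = np.abs(Sb).max()
        assert abs(w1 @ Sw @ w2) <= 1e-8 * scale_w
        assert abs(w1 @ Sb @ w2) <= 1e-8 * scale_b
        assert fisher_objective(model.projection, Sw, Sb) == pytest.approx(
            model.eigenvalues[0] * model.eigenvalues[1], rel=1e-8
        )

    def test_rank_bound_enforced(self):
        with pytest.raises(ValueError, match="K - 1"):
            fit_lda(SIX_POINTS, d=3)

    def test_singular_within_scatter_advises_shrinkage(self):
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_lda(SIX_POINTS, d=1, shrinkage=0.0)

    def test_translation_invariance(self, rng):
        table = _random_classes(rng)
        shift = rng.normal(0, 10, size=2)
        shifted = _table(table.values + shift, table.labels)
        m1, m2 = fit_lda(table, d=2), fit_lda(shifted, d=2)
        np.testing.assert_allclose(m1.within_scatter, m2.within_scatter, rtol=1e-8, atol=1e-6)
        np.testing.assert_allclose(m1.between_scatter, m2.between_scatter, rtol=1e-8, atol=1e-6)
        # identical span: projection matrices agree up to column-wise sign
        np.testing.assert_allclose(np.abs(m1.projection), np.abs(m2.projection), atol=1e-6)

    def test_eigenvalues_sorted_and_nonnegative(self, rng):
        model = fit_lda(_random_classes(rng, n_dim=6), d=2)
        assert model.eigenvalues[0] >= model.eigenvalues[1] >= -1e-10

    def test_matches_sklearn_eigen_solver_subspace(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        table = _random_classes(rng, n_per=60, n_dim=5)
        ours = fit_lda(table, d=2, shrinkage=0.0).projection
        sk = LinearDiscriminantAnalysis(solver="eigen")
        sk.fit(table.values, table.labels)
        theirs = sk.scalings_[:, :2]
        # principal angles between the two 2-D subspaces should vanish
        q1, _ = np.linalg.qr(ours)
        q2, _ = np.linalg.qr(theirs)
        sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert np.all(sv >= 1 - 1e-8)

    def test_deterministic_projection(self, rng):
        table = _random_classes(rng)
        a = fit_lda(table, d=2).projection
        b = fit_lda(table, d=2).projection
        assert np.array_equal(a, b)


class TestTransform:
    def test_leading_component_maximizes_separation(self, rng):
        table = _random_classes(rng, n_per=80, n_dim=4, spread=0.7)
        model = fit_lda(table, d=2)
        projected = transform(model, table)

        def ratio(col, labels):
            overall = col.mean()
            between = sum(
                (col[labels == c].size) * (col[labels == c].mean() - overall) ** 2
                for c in np.unique(labels)
            )
            within = sum(
                ((col[labels == c] - col[labels == c].mean()) ** 2).sum()
                for c in np.unique(labels)
            )
            return between / within

        best_feature = max(ratio(table.values[:, j], table.labels) for j in range(4))
        assert ratio(projected.values[:, 0], table.labels) >= best_feature

    def test_no_reestimation_on_new_data(self, rng):
        table = _random_classes(rng)
        model = fit_lda(table, d=2)
        other = _table(table.values + 3.0, table.labels)
        out = transform(model, other)
        expected = (other.values - model.global_mean) @ model.projection
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert all(m.feature_kind == "lda_component" for m in out.feature_meta)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_lda(_random_classes(rng), d=2)
        bad = _table(np.zeros((4, 5)), [0, 1, 2, 0])
        with pytest.raises(ValueError, match="expects 2"):
            transform(model, bad)

    def test_save_load_round_trip(self, tmp_path, rng):
        model = fit_lda(_random_classes(rng), d=2)
        p = tmp_path / "model.json"
        model.save(p)
        back = LDAModel.load(p)
        np.testing.assert_allclose(back.projection, model.projection, atol=1e-15)
        np.testing.assert_allclose(back.global_mean, model.global_mean, atol=1e-15)
        np.testing.assert_allclose(back.eigenvalues, model.eigenvalues, atol=1e-15)
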