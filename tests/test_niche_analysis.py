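"""Diffusion components, label transfer, composition, concordance, bASW."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from spatialcov import (
    aot_knn_label_transfer,
    batch_asw,
    compute_covet,
    diffusion_components,
    expression_environment_concordance,
    niche_composition,
    pairwise_aot,
)


class TestDiffusionComponents:
    def test_recovers_1d_gradient(self, rng):
        """DC1 of points along a noisy 1D gradient tracks the gradient."""
        t = np.sort(rng.random(150))
        features = np.stack([t, 0.05 * rng.standard_normal(150),
                             0.05 * rng.standard_normal(150)], axis=1)
        res = diffusion_components(features, k=15, m=3)
        rho = spearmanr(t, res.components[:, 0]).statistic
        assert abs(rho) > 0.95

    def test_sign_convention_deterministic(self, rng):
        features = rng.random((80, 5))
        a = diffusion_components(features, k=10, m=2)
        b = diffusion_components(features, k=10, m=2)
        np.testing.assert_array_equal(a.components, b.components)

    def test_row_permutation_equivariance(self, rng):
        features = rng.random((60, 4))
        perm = rng.permutation(60)
        a = diffusion_components(features, k=10, m=2)
        b = diffusion_components(features[perm], k=10, m=2)
        np.testing.assert_allclose(a.components[perm], b.components, atol=1e-8)

    def test_disconnected_graph_warns(self, rng):
        blob = rng.random((30, 2))
        features = np.vstack([blob, blob + 1e6])
        with pytest.warns(UserWarning, match="connected components"):
            res = diffusion_components(features, k=5, m=2)
        assert np.isnan(res.components).any()

    def test_needs_more_rows_than_components(self, rng):
        with pytest.raises(ValueError):
            diffusion_components(rng.random((4, 3)), m=5)

    def test_flatten_identity_with_explicit_aot(self, small_covet):
        """Diffusion on flattened roots == diffusion under explicit AOT
        distances (the squared-Euclidean identity)."""
        flat = small_covet.flat_sqrt()[:100]
        res_flat = diffusion_components(flat, k=15, m=2)
        # independent route: explicit pairwise AOT -> classical MDS-style
        # check that the same neighbourhoods induce the same components
        import spatialcov.covet as cv

        sub = cv.CovetTensor(sigma=small_covet.sigma[:100],
                             sigma_sqrt=small_covet.sigma_sqrt[:100],
                             global_mean=small_covet.global_mean, k=8)
        d2 = pairwise_aot(sub)
        # AOT distances equal squared Euclidean distances of flat vectors,
        # so k-NN graphs agree and components must match
        from sklearn.metrics import pairwise_distances

        np.testing.assert_allclose(
            d2, pairwise_distances(flat, metric="sqeuclidean"), atol=1e-8
        )
        res_flat2 = diffusion_components(flat, k=15, m=2)
        np.testing.assert_allclose(res_flat.components, res_flat2.components)


class TestLabelTransfer:
    def test_identical_item_inherits_label(self, rng):
        train = rng.random((10, 3, 3))
        labels = np.arange(10)
        pred = aot_knn_label_transfer(train, labels, train[[4]], k=1)
        assert pred[0] == 4

    def test_two_archetypes_separable(self, rng):
        a = np.eye(4) * 5
        b = np.ones((4, 4)) + np.eye(4)
        train = np.stack([a + 0.05 * rng.standard_normal((4, 4)) for _ in range(20)]
                         + [b + 0.05 * rng.standard_normal((4, 4)) for _ in range(20)])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        test = np.stack([a + 0.05 * rng.standard_normal((4, 4)) for _ in range(10)]
                        + [b + 0.05 * rng.standard_normal((4, 4)) for _ in range(10)])
        pred = aot_knn_label_transfer(train, labels, test, k=5)
        truth = np.array(["a"] * 10 + ["b"] * 10)
        assert (pred == truth).mean() > 0.9

    def test_label_permutation_consistency(self, rng):
        train = rng.random((15, 2, 2))
        labels = rng.integers(0, 3, size=15)
        test = rng.random((8, 2, 2))
        mapping = {0: 10, 1: 11, 2: 12}
        p1 = aot_knn_label_transfer(train, labels, test, k=3)
        p2 = aot_knn_label_transfer(
            train, np.vectorize(mapping.get)(labels), test, k=3
        )
        np.testing.assert_array_equal(np.vectorize(mapping.get)(p1), p2)

    def test_k_larger_than_train_rejected(self, rng):
        with pytest.raises(ValueError):
            aot_knn_label_transfer(rng.random((3, 2, 2)), np.arange(3),
                                   rng.random((1, 2, 2)), k=5)


class TestNicheComposition:
    def test_rows_sum_to_niche_size(self, small_tissue, small_covet):
        comp, cats = niche_composition(
            small_tissue.cell_type, small_tissue.coords, small_covet.sigma_sqrt
        )
        np.testing.assert_allclose(comp.sum(axis=1), 8.0)
        assert len(cats) == len(set(small_tissue.cell_type.tolist()))

    def test_normalized_rows_sum_to_one(self, small_tissue, small_covet):
        comp, _ = niche_composition(
            small_tissue.cell_type, small_tissue.coords, small_covet.sigma_sqrt,
            normalize=True,
        )
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)

    def test_query_identical_to_spatial_cell(self, small_tissue, small_covet):
        comp, _ = niche_composition(
            small_tissue.cell_type, small_tissue.coords, small_covet.sigma_sqrt
        )
        reg, _ = niche_composition(
            small_tissue.cell_type, small_tissue.coords, small_covet.sigma_sqrt,
            covet_sqrt_query=small_covet.sigma_sqrt[[17]], k_reg=1,
        )
        np.testing.assert_allclose(reg[0], comp[17])

    def test_homogeneous_tissue_concentrates(self, rng):
        coords = rng.random((64, 2))
        labels = np.zeros(64, dtype=int)
        comp, cats = niche_composition(labels, coords, rng.random((64, 2, 2)))
        assert comp.shape == (64, 1)
        np.testing.assert_allclose(comp[:, 0], 8.0)

    def test_unlabeled_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            niche_composition(np.zeros(3), rng.random((10, 2)),
                              rng.random((10, 2, 2)))


class TestConcordance:
    def test_identical_features_give_ari_one(self, rng):
        x = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(8, 1, (30, 4))])
        x = np.abs(x)
        # environment features set to the (log) expression features: the two
        # clusterings see identical inputs with identical seeds
        score = expression_environment_concordance(x, np.log1p(x), n_clusters=2,
                                                   restarts=3, seed=0)
        assert score == pytest.approx(1.0)

    def test_independent_features_give_ari_near_zero(self, rng):
        expr = np.abs(rng.standard_normal((120, 5)))
        env = rng.standard_normal((120, 9))
        score = expression_environment_concordance(expr, env, n_clusters=4,
                                                   restarts=3, seed=0)
        assert abs(score) < 0.1

    def test_restart_count(self, rng):
        # 10 restarts per side -> 100 pairings; just confirm it runs with
        # the defaults and returns a bounded score
        expr = np.abs(rng.standard_normal((60, 4)))
        score = expression_environment_concordance(expr, expr.copy(),
                                                   n_clusters=3, seed=1)
        assert -0.5 <= score <= 1.0

    def test_too_few_cells(self, rng):
        with pytest.raises(ValueError):
            expression_environment_concordance(np.ones((3, 2)),
                                               np.ones((3, 4)), n_clusters=5)


class TestBatchAsw:
    def _latent(self, rng, separated: bool):
        n = 120
        ct = np.repeat(["t1", "t2"], n // 2)
        mod = np.tile(["sc", "st"], n // 2)
        base = np.where(ct == "t1", 0.0, 20.0)[:, None] * np.ones((n, 12))
        lat = base + rng.standard_normal((n, 12))
        if separated:
            lat += np.where(mod == "sc", 0.0, 200.0)[:, None]
        return lat, mod, ct

    def test_interleaved_modalities_score_high(self, rng):
        lat, mod, ct = self._latent(rng, separated=False)
        assert batch_asw(lat, mod, ct) > 0.85

    def test_separated_modalities_score_low(self, rng):
        lat, mod, ct = self._latent(rng, separated=True)
        assert batch_asw(lat, mod, ct) < 0.1

    def test_rotation_invariance(self, rng):
        lat, mod, ct = self._latent(rng, separated=False)
        Q = np.linalg.qr(rng.standard_normal((12, 12)))[0]
        assert batch_asw(lat, mod, ct) == pytest.approx(
            batch_asw(lat @ Q, mod, ct), abs=1e-6
        )

    def test_single_modality_type_excluded(self, rng):
        lat = rng.standard_normal((40, 6))
        mod = np.array(["sc"] * 20 + ["st"] * 20)
        ct = np.array(["only_sc"] * 20 + ["shared"] * 20)
        with pytest.warns(UserWarning, match="only_sc"):
            with pytest.raises(ValueError):
                batch_asw(lat, mod, ct)


def test_gradient_preset_dc1_recovers_axis():
    """On gradient-structured tissue, the first diffusion component of the
    measured niche covariances tracks the planted spatial axis."""
    from spatialcov.synthetic import PRESETS, simulate_tissue

    tissue = simulate_tissue(seed=5, **PRESETS["gradient"])
    cv = compute_covet(tissue.counts_panel, tissue.coords, k=8, log1p=True)
    res = diffusion_components(cv.flat_sqrt(), k=30, m=2)
    rho = spearmanr(tissue.gradient, res.components[:, 0]).statistic
    assert abs(rho) > 0.8
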