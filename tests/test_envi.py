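"""Conditional VAE: forward contracts, ELBO oracle, training and inference."""

import numpy as np
import pytest

from spatialcov import (
    EnviConfig,
    EnviModel,
    aot_distance,
    compute_covet,
    dissociate,
    simulate_tissue,
)
from spatialcov.distributions import nb_log_pmf, poisson_log_pmf
from spatialcov.envi import environment_log_density, select_hvg, train


SC_GENES = [f"g{i:04d}" for i in range(12)]
ST_GENES = SC_GENES[:6]


def tiny_model(seed=0, **kw):
    cfg = EnviConfig(latent_dim=4, hidden_width=8, hidden_layers=2,
                     batch_size=8, train_steps=5, hvg_count=12, seed=seed, **kw)
    return EnviModel(cfg, SC_GENES, ST_GENES)


@pytest.fixture(scope="module")
def fitted():
    """A quickly fitted small model on a coupled synthetic pair."""
    tissue = simulate_tissue(n_cells=400, G_full=30, G_panel=20,
                             coupling_strength=1.5, seed=11)
    diss = dissociate(tissue, dropout_rate=0.1, seed=12)
    cfg = EnviConfig(latent_dim=16, hidden_width=64, hidden_layers=2,
                     batch_size=64, train_steps=250, hvg_count=30, seed=0)
    model = train(diss["counts"], diss["gene_ids"], tissue.counts_panel,
                  list(tissue.panel), tissue.coords, config=cfg)
    return model, tissue, diss


class TestEncoder:
    def test_posterior_shapes_and_determinism(self, rng):
        m = tiny_model()
        x = rng.random((3, 6))
        mu1, sd1 = m.encode(x, c=0)
        mu2, sd2 = m.encode(x, c=0)
        assert mu1.shape == (3, 4) and sd1.shape == (3, 4)
        np.testing.assert_array_equal(mu1.data, mu2.data)
        assert (sd1.data > 0).all()

    def test_modality_flag_changes_posterior(self, rng):
        m = tiny_model()
        x = rng.random((3, 6))
        mu0, _ = m.encode(x, c=0)
        mu1, _ = m.encode(x, c=1)
        assert not np.allclose(mu0.data, mu1.data)

    def test_wrong_panel_width_rejected(self):
        m = tiny_model()
        with pytest.raises(ValueError):
            m.encode(np.zeros((2, 5)), c=0)

    def test_default_latent_dimension_is_512(self):
        assert EnviConfig().latent_dim == 512
        assert EnviConfig().hidden_width == 1024
        assert EnviConfig().hidden_layers == 3

    def test_beta_escalates_below_ten_thousand_cells(self):
        cfg = EnviConfig()
        assert cfg.resolved_beta(9_999) == 1.0
        assert cfg.resolved_beta(20_000) == 0.3


class TestReparameterize:
    def test_zero_eps_returns_mean(self, rng):
        m = tiny_model()
        mu, sd = m.encode(rng.random((2, 6)), c=1)
        l = m.reparameterize(mu, sd, np.zeros((2, 4)))
        np.testing.assert_allclose(l.data, mu.data)

    def test_sample_mean_approaches_mu(self, rng):
        m = tiny_model()
        mu, sd = m.encode(rng.random((1, 6)), c=1)
        eps = rng.standard_normal((10_000, 4))
        draws = mu.data + eps * sd.data
        np.testing.assert_allclose(
            draws.mean(axis=0), mu.data[0], atol=4 * sd.data.max() / 100
        )


class TestEnvironmentHead:
    def test_gramian_is_psd_and_square(self, rng):
        m = tiny_model()
        mu, _ = m.encode(rng.random((4, 6)), c=1)
        gram = m.decode_env(mu).data
        assert gram.shape == (4, 6, 6)
        assert np.linalg.eigvalsh(gram).min() > -1e-10
        np.testing.assert_allclose(gram, np.swapaxes(gram, 1, 2), atol=1e-12)

    def test_log_density_zero_at_match(self, rng):
        target = rng.random((3, 3))
        assert environment_log_density(target, target) == 0.0

    def test_penalty_is_half_aot(self, rng):
        from spatialcov.covet import matrix_sqrt_psd
        from conftest import random_psd

        a = matrix_sqrt_psd(random_psd(rng, 4))
        b = matrix_sqrt_psd(random_psd(rng, 4))
        assert -environment_log_density(a, b) == pytest.approx(
            0.5 * aot_distance(a, b)
        )

    def test_quadratic_scaling(self, rng):
        t = rng.random((3, 3))
        r = rng.random((3, 3))
        p1 = -environment_log_density(t, t + r)
        p2 = -environment_log_density(t, t + 2 * r)
        assert p2 == pytest.approx(4 * p1)


class TestElbo:
    def test_matches_term_by_term_oracle(self, rng):
        """Literal re-summation of the four ELBO terms, with an
        independently re-implemented forward pass."""
        m = tiny_model()
        beta = 0.7
        half = 2
        x_sc = rng.poisson(3.0, size=(half, 12)).astype(float)
        x_st = rng.poisson(3.0, size=(half, 6)).astype(float)
        target = rng.random((half, 6, 6))
        eps_sc = rng.standard_normal((half, 4))
        eps_st = rng.standard_normal((half, 4))
        loss = m.elbo_loss(x_sc, x_st, target, eps_sc, eps_st, beta).data

        def forward(mlp, x):
            h = x
            for i, (W, b) in enumerate(zip(mlp.weights, mlp.biases)):
                h = h @ W.data + b.data
                if i < len(mlp.weights) - 1:
                    h = np.maximum(h, 0)
            return h

        softplus = lambda z: np.logaddexp(0, z)
        sigmoid = lambda z: 0.5 * (1 + np.tanh(0.5 * z))

        def posterior(x, c):
            inp = np.hstack([np.log1p(x), np.full((len(x), 1), float(c))])
            out = forward(m.encoder, inp)
            return out[:, :4], softplus(out[:, 4:]) + 1e-5

        mu_sc, sd_sc = posterior(x_sc[:, :6], 1)
        mu_st, sd_st = posterior(x_st, 0)
        l_sc = mu_sc + eps_sc * sd_sc
        l_st = mu_st + eps_st * sd_st

        out_sc = forward(m.dec_exp, np.hstack([l_sc, np.ones((half, 1))]))
        r = softplus(out_sc[:, :12]) + 1e-4
        p = sigmoid(out_sc[:, 12:24])
        ll_sc = nb_log_pmf(x_sc, r, p).sum(axis=1).mean()

        out_st = forward(m.dec_exp, np.hstack([l_st, np.zeros((half, 1))]))
        lam = softplus(out_st[:, :6]) + 1e-4
        ll_st = poisson_log_pmf(x_st, lam).sum(axis=1).mean()

        chol = forward(m.dec_env, l_st)
        rows, cols = np.tril_indices(6)
        ll_env = 0.0
        for i in range(half):
            L = np.zeros((6, 6))
            L[rows, cols] = chol[i]
            ll_env += environment_log_density(target[i], L @ L.T)
        ll_env /= half

        def kl(mu, sd):
            return 0.5 * (mu**2 + sd**2 - 2 * np.log(sd) - 1).sum(axis=1).mean()

        expected = -(ll_sc + ll_st + ll_env) + beta * 0.5 * (
            kl(mu_sc, sd_sc) + kl(mu_st, sd_st)
        )
        assert loss == pytest.approx(expected, rel=1e-10)

    def test_standard_posterior_has_zero_kl_term(self):
        # closed diagonal-Gaussian form: mu=0, sigma=1 contributes nothing
        mu, sd = np.zeros((2, 4)), np.ones((2, 4))
        kl = 0.5 * (mu**2 + sd**2 - 2 * np.log(sd) - 1).sum()
        assert kl == 0.0


class TestTraining:
    def test_loss_decreases_on_smoke_fixture(self, fitted):
        model, _, _ = fitted
        first = np.mean(model.loss_history[:20])
        last = np.mean(model.loss_history[-20:])
        assert last < first

    def test_gene_scope_starts_with_shared_panel(self, fitted):
        model, tissue, _ = fitted
        assert model.sc_genes[: model.g_st] == list(tissue.panel)

    def test_empty_gene_intersection_rejected(self, rng):
        counts = rng.poisson(2.0, size=(70, 4)).astype(float)
        coords = rng.random((70, 2))
        with pytest.raises(ValueError, match="intersect"):
            train(counts, ["a", "b", "c", "d"], counts, ["w", "x", "y", "z"],
                  coords, EnviConfig(latent_dim=4, hidden_width=8,
                                     batch_size=4, train_steps=1))


class TestInference:
    def test_untrained_model_refuses(self):
        m = tiny_model()
        with pytest.raises(RuntimeError):
            m.impute_genes(np.zeros((2, 6)))
        with pytest.raises(RuntimeError):
            m.infer_covet(np.zeros((2, 6)))

    def test_imputation_contract(self, fitted):
        model, tissue, _ = fitted
        imp = model.impute_genes(tissue.counts_panel)
        assert imp.shape == (tissue.n_cells, model.g_sc)
        assert (imp >= 0).all()

    def test_imputation_self_consistency(self, fitted):
        """Imputed panel genes correlate with their observed spatial counts."""
        model, tissue, _ = fitted
        imp = model.impute_genes(tissue.counts_panel)
        cors = []
        for j, g in enumerate(model.st_genes):
            obs = tissue.counts_panel[:, list(tissue.panel).index(g)]
            if obs.std() > 0 and imp[:, j].std() > 0:
                cors.append(np.corrcoef(obs, imp[:, j])[0, 1])
        assert np.mean(cors) > 0.2

    def test_inferred_covet_is_psd_with_right_shape(self, fitted):
        model, _, diss = fitted
        pos = {g: i for i, g in enumerate(diss["gene_ids"])}
        panel = diss["counts"][:50, [pos[g] for g in model.st_genes]]
        inferred = model.infer_covet(panel)
        assert inferred.shape == (50, model.g_st, model.g_st)
        assert np.linalg.eigvalsh(inferred).min() > -1e-8


def test_save_load_roundtrip(tmp_path, rng):
    m = tiny_model(seed=3)
    m.trained = True
    path = tmp_path / "model.h5"
    m.save(path)
    loaded = EnviModel.load(path)
    x = rng.random((3, 6))
    np.testing.assert_array_equal(
        m.encode(x, c=0)[0].data, loaded.encode(x, c=0)[0].data
    )
    assert loaded.sc_genes == m.sc_genes and loaded.trained


def test_select_hvg_prefers_variable_genes(rng):
    n = 200
    counts = rng.poisson(5.0, size=(n, 5)).astype(float)
    counts[:, 2] = np.where(rng.random(n) < 0.5, 0.0, 100.0)  # bimodal gene
    idx = select_hvg(counts, 1)
    assert idx.tolist() == [2]
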