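"""Conditional variational autoencoder integrating dissociated and spatial
transcriptomics.

Both modalities are embedded into one latent space by a single encoder that
receives, besides the expression over the shared ("imaged") gene panel, an
auxiliary binary neuron marking the modality (0 = spatial, 1 = dissociated).
Two decoders reconstruct from the latent:

* an *expression* decoder whose output layer parameterises a count
  likelihood per gene — negative binomial for dissociated data (dropout and
  overdispersion), Poisson for imaging data (high capture rate) by default,
  with zero-inflated NB and normal heads available.  Only the first ``g_st``
  output neurons (the imaged panel) are shared between modalities; the
  remaining genes are trained from the dissociated data alone, which lets
  the model reconstruct the full transcriptome from panel-only input.
* an *environment* decoder that reconstructs the niche-covariance (COVET)
  square root of spatial cells.  Its output parameterises a lower-triangular
  Cholesky factor L, and the Gramian L L^T is the mean of an isotropic
  Gaussian over matrix square roots — whose log density is exactly the
  (negative half) AOT distance, tying the reconstruction geometry to the
  niche metric.

Training maximises the evidence lower bound: the two modality likelihoods
plus the environment term minus a beta-weighted KL to a standard-normal
prior.  After training, unimaged genes are imputed for spatial cells by
decoding their latent with the dissociated-modality flag, and spatial
context is inferred for dissociated cells by running their latent through
the environment decoder.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from ._autodiff import Adam, Tensor, concat
from .covet import compute_covet
from .distributions import nb_mean

__all__ = ["EnviConfig", "EnviModel", "train", "select_hvg",
           "environment_log_density"]


def environment_log_density(target_sqrt: np.ndarray, gram: np.ndarray) -> float:
    """Log density (up to the additive constant) of an observed COVET square
    root under the environment head N(L L^T, I): -1/2 ||target - L L^T||_F^2.

    Because both arguments are PSD square roots, this equals minus half the
    AOT distance between the covariances they imply.
    """
    target_sqrt = np.asarray(target_sqrt, dtype=float)
    gram = np.asarray(gram, dtype=float)
    if target_sqrt.shape != gram.shape:
        raise ValueError(f"shape mismatch: {target_sqrt.shape} vs {gram.shape}")
    resid = gram - target_sqrt
    return float(-0.5 * np.sum(resid * resid))

_EPS = 1e-4  # floor for strictly positive head parameters
_CHOL_RIDGE = 1e-6  # ridge making the mean COVET root strictly PD


@dataclass
class EnviConfig:
    """Hyper-parameters of the model and its training schedule.

    ``beta`` left as None resolves at fit time to 0.3, escalated to 1.0
    when the combined dataset holds fewer than 10,000 cells (small data
    benefit from a stronger prior).
    """

    latent_dim: int = 512
    hidden_layers: int = 3
    hidden_width: int = 1024
    beta: float | None = None
    sc_likelihood: str = "nb"  # nb | zinb | poisson | normal
    spatial_likelihood: str = "poisson"  # poisson | nb | zinb | normal
    train_steps: int = 16384
    batch_size: int = 1024  # half per modality
    lr: float = 1e-3
    lr_final: float = 1e-4  # used for the last quarter of steps
    hvg_count: int = 2048
    k_niche: int = 8
    #: hidden depth of the environment decoder; None = same as hidden_layers
    env_hidden_layers: int | None = None
    #: global gradient-norm clip; None disables
    grad_clip: float | None = None
    covet_transform: str = "log1p"  # transform before ShiftCov: log1p | none
    #: rescale COVET-root targets to unit entry s.d. so the unit-variance
    #: environment Gaussian weights them on their natural scale
    covet_standardize: bool = True
    input_transform: str = "log1p"  # encoder input transform
    seed: int = 0

    def __post_init__(self):
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (half per modality)")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        for name, val in (("sc", self.sc_likelihood), ("spatial", self.spatial_likelihood)):
            if val not in ("nb", "zinb", "poisson", "normal"):
                raise ValueError(f"unknown {name}_likelihood {val!r}")

    def resolved_beta(self, n_total: int) -> float:
        if self.beta is not None:
            return self.beta
        return 1.0 if n_total < 10_000 else 0.3


# ---------------------------------------------------------------------------
# network building blocks


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _MLP:
    """Dense ReLU network; parameters are autodiff tensors."""

    def __init__(self, rng, dim_in: int, dim_hidden: int, n_hidden: int, dim_out: int):
        dims = [dim_in] + [dim_hidden] * n_hidden + [dim_out]
        self.weights = [
            Tensor(_glorot(rng, a, b), requires_grad=True)
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.biases = [
            Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]
        ]

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = h.relu()
        return h

    @property
    def params(self) -> list[Tensor]:
        return self.weights + self.biases


def _with_flag(x: Tensor, c: float) -> Tensor:
    col = Tensor(np.full((x.shape[0], 1), float(c)))
    return concat([x, col], axis=1)


def _tril_embed(flat: Tensor, g: int, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Scatter (B, g(g+1)/2) Cholesky entries into (B, g, g) lower triangles."""
    data = np.zeros((flat.shape[0], g, g))
    data[:, rows, cols] = flat.data

    def backward(grad, out):
        return (grad[:, rows, cols],)

    return flat._make(data, (flat,), backward)


# differentiable log-likelihood terms (cross-checked against
# spatialcov.distributions in the tests)


def _nb_ll(k: np.ndarray, raw_r: Tensor, logit_p: Tensor) -> Tensor:
    r = raw_r.softplus() + _EPS
    kt = Tensor(k)
    log_p = -(-logit_p).softplus()
    log_1mp = -logit_p.softplus()
    return (kt + r).gammaln() - r.gammaln() - Tensor(_lgamma(k + 1)) \
        + kt * log_1mp + r * log_p


def _poisson_ll(k: np.ndarray, raw_lam: Tensor) -> Tensor:
    lam = raw_lam.softplus() + _EPS
    return Tensor(k) * lam.log() - lam - Tensor(_lgamma(k + 1))


def _zinb_ll(k: np.ndarray, raw_r: Tensor, logit_p: Tensor, logit_pi: Tensor) -> Tensor:
    nb = _nb_ll(k, raw_r, logit_p)
    pi = logit_pi.sigmoid()
    r = raw_r.softplus() + _EPS
    log_p = -(-logit_p).softplus()
    nb_zero = r * log_p  # NB log pmf at k = 0
    zero_branch = (pi + (1.0 - pi) * nb_zero.exp() + 1e-12).log()
    nonzero_branch = (1.0 - pi + 1e-12).log() + nb
    mask0 = (k == 0).astype(float)
    return Tensor(mask0) * zero_branch + Tensor(1.0 - mask0) * nonzero_branch


def _normal_ll(k: np.ndarray, mu: Tensor, raw_logvar: Tensor) -> Tensor:
    var = raw_logvar.exp() + _EPS
    diff = Tensor(k) - mu
    return -0.5 * (var.log() + np.log(2 * np.pi) + diff * diff / var)


def _lgamma(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def select_hvg(counts: np.ndarray, n_top: int) -> np.ndarray:
    """Indices of the most variable genes, by variance of log1p expression
    after library-size normalisation to the median total count."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    scaled = counts / lib * np.median(lib)
    var = np.log1p(scaled).var(axis=0)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[: min(n_top, counts.shape[1])])


# ---------------------------------------------------------------------------
# model


class EnviModel:
    """Trained (or trainable) conditional VAE over two modalities.

    Use :func:`train` to construct and fit in one call.  ``sc_genes`` is the
    modelled dissociated gene scope (shared panel first, then the remaining
    highly variable genes); ``st_genes`` is the shared imaged panel.
    """

    def __init__(self, config: EnviConfig, sc_genes: list[str], st_genes: list[str]):
        self.config = config
        self.sc_genes = list(sc_genes)
        self.st_genes = list(st_genes)
        self.g_sc = len(sc_genes)
        self.g_st = len(st_genes)
        if self.sc_genes[: self.g_st] != self.st_genes:
            raise ValueError("sc gene scope must start with the shared panel")
        self.trained = False
        self.loss_history: list[float] = []
        #: multiplicative factor applied to COVET-root targets at fit time;
        #: inference divides by it so outputs are on the measured scale
        self.covet_scale = 1.0
        rng = np.random.default_rng(config.seed)
        d, w, nh = config.latent_dim, config.hidden_width, config.hidden_layers
        self.encoder = _MLP(rng, self.g_st + 1, w, nh, 2 * d)
        # expression decoder: 3 blocks of g_sc neurons (mean parameter,
        # second parameter, zero-inflation); heads consume what they need
        self.dec_exp = _MLP(rng, d + 1, w, nh, 3 * self.g_sc)
        n_chol = self.g_st * (self.g_st + 1) // 2
        nh_env = nh if config.env_hidden_layers is None else config.env_hidden_layers
        self.dec_env = _MLP(rng, d, w, nh_env, n_chol)
        self._tril = np.tril_indices(self.g_st)
        # per-gene log-variance for normal heads
        self.logvar_sc = Tensor(np.zeros(self.g_sc), requires_grad=True)
        self.logvar_st = Tensor(np.zeros(self.g_st), requires_grad=True)

    def init_output_biases(self, sc_gene_means: np.ndarray,
                           covet_sqrt_mean: np.ndarray) -> None:
        """Start the decoders at the data means.

        The expression head's rate-parameter bias is set to the inverse
        softplus of each gene's mean count, and the environment head's bias
        to the Cholesky factor of the mean COVET square root, so training
        spends its steps on per-cell deviations rather than rebuilding the
        global mean through the nonlinear output maps.
        """
        mean = np.clip(np.asarray(sc_gene_means, dtype=float), 1e-3, None)
        with np.errstate(over="ignore"):
            inv_softplus = np.where(mean > 20, mean, np.log(np.expm1(np.minimum(mean, 20.0))))
        self.dec_exp.biases[-1].data[: self.g_sc] = inv_softplus
        target = np.asarray(covet_sqrt_mean, dtype=float)
        target = target + _CHOL_RIDGE * np.eye(target.shape[0])
        L0 = np.linalg.cholesky(target)
        rows, cols = self._tril
        self.dec_env.biases[-1].data[:] = L0[rows, cols]

    # -- forward passes --------------------------------------------------
    @property
    def params(self) -> list[Tensor]:
        return (
            self.encoder.params + self.dec_exp.params + self.dec_env.params
            + [self.logvar_sc, self.logvar_st]
        )

    def encode(self, x: np.ndarray, c: int) -> tuple[Tensor, Tensor]:
        """Posterior (mu, sigma) for expression over the shared panel."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.g_st:
            raise ValueError(
                f"encoder expects the {self.g_st}-gene shared panel, got {x.shape[1]}"
            )
        if c not in (0, 1):
            raise ValueError("modality flag c must be 0 (spatial) or 1 (dissociated)")
        out = self.encoder(_with_flag(Tensor(x), c))
        d = self.config.latent_dim
        mu = out[:, :d]
        sigma = out[:, d:].softplus() + 1e-5
        return mu, sigma

    @staticmethod
    def reparameterize(mu: Tensor, sigma: Tensor, eps: np.ndarray) -> Tensor:
        """l = mu + eps * sigma (reparameterisation trick)."""
        return mu + Tensor(eps) * sigma

    def _decode_exp(self, l: Tensor, c: int) -> Tensor:
        return self.dec_exp(_with_flag(l, c))

    def decode_env(self, l: Tensor) -> Tensor:
        """(B, g_st, g_st) Gramians L L^T — PSD means over COVET roots."""
        flat = self.dec_env(l)
        L = _tril_embed(flat, self.g_st, *self._tril)
        return L @ L.T if L.data.ndim == 2 else L @ _batch_T(L)

    def _expression_ll(self, out: Tensor, counts: np.ndarray, likelihood: str,
                       n_genes: int, logvar: Tensor) -> Tensor:
        """Per-batch total log likelihood of counts under the chosen head.

        Uses the first ``n_genes`` columns of each decoder output block, so
        the spatial modality reads only the shared panel neurons.
        """
        g = self.g_sc
        block1 = out[:, :n_genes]
        block2 = out[:, g : g + n_genes]
        block3 = out[:, 2 * g : 2 * g + n_genes]
        if likelihood == "nb":
            ll = _nb_ll(counts, block1, block2)
        elif likelihood == "zinb":
            ll = _zinb_ll(counts, block1, block2, block3)
        elif likelihood == "poisson":
            ll = _poisson_ll(counts, block1)
        elif likelihood == "normal":
            ll = _normal_ll(counts, block1, logvar[:n_genes])
        else:  # pragma: no cover - validated in config
            raise ValueError(likelihood)
        return ll.sum(axis=1).mean()

    def elbo_loss(
        self,
        batch_sc: np.ndarray,
        batch_st: np.ndarray,
        covet_sqrt_st: np.ndarray,
        eps_sc: np.ndarray,
        eps_st: np.ndarray,
        beta: float,
    ) -> Tensor:
        """Negative ELBO over one joint mini-batch (scalar, differentiable).

        Terms: dissociated full-transcriptome likelihood + spatial panel
        likelihood + environment (COVET-root) Gaussian term
        - beta * KL(posterior || N(0, I)), averaged per cell.
        """
        cfg = self.config
        x_sc_in = self._transform(batch_sc[:, : self.g_st])
        x_st_in = self._transform(batch_st)

        mu_sc, sd_sc = self.encode(x_sc_in, c=1)
        mu_st, sd_st = self.encode(x_st_in, c=0)
        l_sc = self.reparameterize(mu_sc, sd_sc, eps_sc)
        l_st = self.reparameterize(mu_st, sd_st, eps_st)

        out_sc = self._decode_exp(l_sc, c=1)
        out_st = self._decode_exp(l_st, c=0)
        ll_sc = self._expression_ll(out_sc, batch_sc, cfg.sc_likelihood,
                                    self.g_sc, self.logvar_sc)
        ll_st = self._expression_ll(out_st, batch_st, cfg.spatial_likelihood,
                                    self.g_st, self.logvar_st)

        mean_env = self.decode_env(l_st)
        resid = mean_env - Tensor(covet_sqrt_st)
        ll_env = -0.5 * (resid * resid).reshape(resid.shape[0], -1).sum(axis=1).mean()

        def kl(mu: Tensor, sd: Tensor) -> Tensor:
            return (0.5 * (mu * mu + sd * sd - 2.0 * sd.log() - 1.0)).sum(axis=1).mean()

        kl_term = 0.5 * (kl(mu_sc, sd_sc) + kl(mu_st, sd_st))
        loss = -(ll_sc + ll_st + ll_env) + beta * kl_term
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss (ll_sc={ll_sc.data:.3g}, ll_st={ll_st.data:.3g}, "
                f"ll_env={ll_env.data:.3g}, kl={kl_term.data:.3g})"
            )
        return loss

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.config.input_transform == "log1p":
            return np.log1p(x)
        return np.asarray(x, dtype=float)

    # -- inference -------------------------------------------------------
    def _require_trained(self):
        if not self.trained:
            raise RuntimeError("model has not been trained")

    def latent(self, counts_panel: np.ndarray, c: int, sample: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        """Latent representation (posterior mean by default)."""
        mu, sd = self.encode(self._transform(counts_panel), c=c)
        if sample:
            rng = rng or np.random.default_rng(self.config.seed)
            return mu.data + rng.standard_normal(mu.shape) * sd.data
        return mu.data

    def impute_genes(self, st_counts: np.ndarray, batch: int = 2048) -> np.ndarray:
        """Full-transcriptome expression for spatial cells.

        The spatial latent is decoded with the dissociated modality flag and
        the head expectation is returned (r(1-p)/p for NB).  Output is
        (n_st, g_sc), nonnegative, over ``sc_genes``.
        """
        self._require_trained()
        st_counts = np.asarray(st_counts, dtype=float)
        rows = []
        for start in range(0, st_counts.shape[0], batch):
            chunk = st_counts[start : start + batch]
            mu, _ = self.encode(self._transform(chunk), c=0)
            out = self._decode_exp(mu, c=1)
            rows.append(self._head_mean(out, self.config.sc_likelihood,
                                        self.g_sc, self.logvar_sc))
        return np.vstack(rows)

    def _head_mean(self, out: Tensor, likelihood: str, n_genes: int,
                   logvar: Tensor) -> np.ndarray:
        g = self.g_sc
        b1 = out.data[:, :n_genes]
        b2 = out.data[:, g : g + n_genes]
        b3 = out.data[:, 2 * g : 2 * g + n_genes]
        softplus = lambda z: np.logaddexp(0.0, z)
        sigmoid = lambda z: 0.5 * (1 + np.tanh(0.5 * z))
        if likelihood == "nb":
            return nb_mean(softplus(b1) + _EPS, np.clip(sigmoid(b2), 1e-6, 1 - 1e-6))
        if likelihood == "zinb":
            mean_nb = nb_mean(softplus(b1) + _EPS, np.clip(sigmoid(b2), 1e-6, 1 - 1e-6))
            return (1.0 - sigmoid(b3)) * mean_nb
        if likelihood == "poisson":
            return softplus(b1) + _EPS
        return np.maximum(b1, 0.0)  # normal head: clipped mean

    def infer_covet(self, sc_counts_panel: np.ndarray, batch: int = 2048) -> np.ndarray:
        """Predicted COVET square roots (n_sc, g_st, g_st) for dissociated
        cells, PSD by construction (Gramian of the Cholesky-factor output)."""
        self._require_trained()
        sc_counts_panel = np.asarray(sc_counts_panel, dtype=float)
        outs = []
        for start in range(0, sc_counts_panel.shape[0], batch):
            chunk = sc_counts_panel[start : start + batch]
            mu, _ = self.encode(self._transform(chunk), c=1)
            outs.append(self.decode_env(mu).data)
        return np.vstack(outs) / self.covet_scale

    # -- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["trained"] = self.trained
            f.attrs["covet_scale"] = self.covet_scale
            f.create_dataset("sc_genes", data=np.array(self.sc_genes, dtype="S"))
            f.create_dataset("st_genes", data=np.array(self.st_genes, dtype="S"))
            for name, tensors in self._param_groups().items():
                grp = f.create_group(name)
                for i, t in enumerate(tensors):
                    grp.create_dataset(str(i), data=t.data)

    def _param_groups(self) -> dict[str, list[Tensor]]:
        return {
            "encoder": self.encoder.params,
            "dec_exp": self.dec_exp.params,
            "dec_env": self.dec_env.params,
            "extra": [self.logvar_sc, self.logvar_st],
        }

    @classmethod
    def load(cls, path: str) -> "EnviModel":
        with h5py.File(path, "r") as f:
            config = EnviConfig(**json.loads(f.attrs["config"]))
            sc_genes = [g.decode() for g in f["sc_genes"][:]]
            st_genes = [g.decode() for g in f["st_genes"][:]]
            model = cls(config, sc_genes, st_genes)
            for name, tensors in model._param_groups().items():
                for i, t in enumerate(tensors):
                    t.data = f[name][str(i)][:]
            model.trained = bool(f.attrs["trained"])
            model.covet_scale = float(f.attrs.get("covet_scale", 1.0))
        return model


def _batch_T(L: Tensor) -> Tensor:
    def backward(g, out):
        return (np.swapaxes(g, -1, -2),)

    return L._make(np.swapaxes(L.data, -1, -2), (L,), backward)


# ---------------------------------------------------------------------------
# training


def align_genes(sc_genes: list[str], st_genes: list[str]) -> tuple[list[str], list[str]]:
    """Case-sensitive intersection of the spatial panel with the dissociated
    gene set, in panel order; returns (shared, dropped_spatial)."""
    sc_set = set(sc_genes)
    shared = [g for g in st_genes if g in sc_set]
    dropped = [g for g in st_genes if g not in sc_set]
    return shared, dropped


def train(
    sc_counts: np.ndarray,
    sc_genes: list[str],
    st_counts: np.ndarray,
    st_genes: list[str],
    coords: np.ndarray,
    config: EnviConfig | None = None,
    covet_sqrt: np.ndarray | None = None,
    verbose: bool = False,
) -> EnviModel:
    """Fit the model on a dissociated and a spatial dataset.

    The dissociated gene scope is the union of the shared panel and the top
    ``hvg_count`` highly variable genes.  Spatial niche covariances (k = 8
    neighbours by default) are computed once up front and their matrix
    square roots are the environment-decoder targets; precomputed roots can
    be passed via ``covet_sqrt``.  Adam with the two-phase learning rate
    (``lr`` then ``lr_final`` for the last quarter of steps); half of every
    batch is drawn from each modality, with replacement.
    """
    config = config or EnviConfig()
    sc_counts = np.asarray(sc_counts, dtype=float)
    st_counts = np.asarray(st_counts, dtype=float)
    if len(sc_genes) != sc_counts.shape[1] or len(st_genes) != st_counts.shape[1]:
        raise ValueError("gene list lengths must match count matrix widths")

    shared, dropped = align_genes(sc_genes, st_genes)
    if not shared:
        raise ValueError("the two gene panels do not intersect")
    if dropped and verbose:
        print(f"dropping {len(dropped)} spatial genes absent from the "
              f"dissociated data: {dropped[:10]}{'...' if len(dropped) > 10 else ''}")

    sc_pos = {g: i for i, g in enumerate(sc_genes)}
    hvg_idx = select_hvg(sc_counts, config.hvg_count)
    hvg_names = [sc_genes[i] for i in hvg_idx]
    scope = shared + [g for g in hvg_names if g not in set(shared)]
    sc_X = sc_counts[:, [sc_pos[g] for g in scope]]
    st_pos = {g: i for i, g in enumerate(st_genes)}
    st_X = st_counts[:, [st_pos[g] for g in shared]]

    if covet_sqrt is None:
        covet = compute_covet(
            st_X, coords, k=config.k_niche,
            log1p=(config.covet_transform == "log1p"),
        )
        covet_sqrt = covet.sigma_sqrt

    model = EnviModel(config, scope, shared)
    if config.covet_standardize:
        sd = float(covet_sqrt.std())
        if sd > 0:
            model.covet_scale = 1.0 / sd
            covet_sqrt = covet_sqrt * model.covet_scale
    model.init_output_biases(sc_X.mean(axis=0), covet_sqrt.mean(axis=0))
    beta = config.resolved_beta(sc_X.shape[0] + st_X.shape[0])
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.lr, clip_norm=config.grad_clip)
    half = config.batch_size // 2
    d = config.latent_dim
    for step in range(config.train_steps):
        opt.lr = config.lr if step < 3 * config.train_steps // 4 else config.lr_final
        idx_sc = rng.integers(0, sc_X.shape[0], size=half)
        idx_st = rng.integers(0, st_X.shape[0], size=half)
        eps_sc = rng.standard_normal((half, d))
        eps_st = rng.standard_normal((half, d))
        loss = model.elbo_loss(
            sc_X[idx_sc], st_X[idx_st], covet_sqrt[idx_st], eps_sc, eps_st, beta
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.loss_history.append(float(loss.data))
        if verbose and (step % 100 == 0 or step == config.train_steps - 1):
            print(f"step {step}: loss {loss.data:.4f}")
    model.trained = True
    return model
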