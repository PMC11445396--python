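"""Count-data log densities used by the expression decoder heads.

Parameterisations follow the decoder outputs: the negative binomial is in
(r, p) form — number of failures r > 0 and success probability p in (0, 1),

    P(k | NB(r, p)) = C(k + r - 1, r - 1) (1 - p)^k p^r,

with expectation r (1 - p) / p.  The zero-inflated variant mixes in a point
mass at zero with weight pi.  These are plain-numpy evaluations used for
scoring and as independent oracles; the differentiable versions inside the
training loss are built from autodiff primitives and cross-checked against
these in the tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "nb_log_pmf",
    "nb_mean",
    "poisson_log_pmf",
    "zinb_log_pmf",
    "normal_log_density",
    "kl_diag_gaussians",
]


def nb_log_pmf(k, r, p) -> np.ndarray:
    """Negative-binomial log pmf in failures/success-probability form."""
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(k < 0) or not np.allclose(k, np.round(k)):
        raise ValueError("k must be nonnegative integers")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly in (0, 1)")
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1)
        + k * np.log1p(-p) + r * np.log(p)
    )


def nb_mean(r, p) -> np.ndarray:
    """Expectation r(1-p)/p of the negative binomial above."""
    return np.asarray(r, dtype=float) * (1.0 - np.asarray(p)) / np.asarray(p)


def poisson_log_pmf(k, lam) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any(k < 0) or not np.allclose(k, np.round(k)):
        raise ValueError("k must be nonnegative integers")
    return k * np.log(lam) - lam - gammaln(k + 1)


def zinb_log_pmf(k, r, p, pi) -> np.ndarray:
    """Zero-inflated negative binomial: point mass at 0 with weight pi."""
    k = np.asarray(k, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi >= 1):
        raise ValueError("pi must lie in [0, 1)")
    nb = nb_log_pmf(k, r, p)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi * np.ones_like(nb))
        zero_branch = logsumexp(
            np.stack([log_pi, np.log1p(-pi) * np.ones_like(nb) + nb]), axis=0
        )
    nonzero_branch = np.log1p(-pi) + nb
    return np.where(k == 0, zero_branch, nonzero_branch)


def normal_log_density(x, mu, var) -> np.ndarray:
    x, mu, var = (np.asarray(a, dtype=float) for a in (x, mu, var))
    if np.any(var <= 0):
        raise ValueError("variance must be positive")
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def kl_diag_gaussians(mu, sigma) -> float:
    """Closed-form KL( N(mu, diag sigma^2) || N(0, I) ), summed over dims."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return float(0.5 * np.sum(mu**2 + sigma**2 - 2 * np.log(sigma) - 1.0))
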