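"""Multinomial-probit kernel classifier with auxiliary-variable Gibbs sampling.

Model
-----
For m classes, each class c carries an independent latent function with a
Gaussian-process prior over the training inputs,

    f_c ~ N(0, s * (K + jitter * I)),

where K is the (trace-normalised) linear kernel and s the latent prior scale.
Observed labels follow the multinomial probit link,

    y_n = argmax_c ( f_c(x_n) + eps_nc ),   eps_nc ~ N(0, 1) i.i.d.

Inference is Albert–Chib-style auxiliary-variable Gibbs sampling: the noisy
latents a_nc = f_nc + eps_nc are sampled from truncated normals consistent
with the observed argmax, then the latent functions are drawn from their
Gaussian conditional.  Because prior covariance and identity commute, the
conditional of f given a has mean M a and covariance M with
M = S (S + I)^{-1}, S = s (K + jitter I), which keeps each sweep to two
matrix products per class block.

Predictions integrate both the conditional Gaussian of the test latents and
the probit noise on a Gauss–Hermite grid: per posterior draw the test-latent
conditional mean is computed per class, the (class-shared) conditional
variance is folded into the probit noise, and
P(class = c) = E_u[ prod_{j != c} Phi(u + (mu_c - mu_j)/sd) ] with u ~ N(0,1).

Hyperparameters (s, jitter) are fixed, not sampled — a deliberate departure
from a fully Bayesian treatment that keeps cross-validation × permutation
loops tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import cho_factor, cho_solve
from scipy.special import ndtr, ndtri

from .features import KernelMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int
    n_samples: int = 2000
    n_burnin: int = 500
    seed: int = 0
    kernel_jitter: float | None = None   # default: 1e-6 * mean kernel diagonal
    latent_prior_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_samples < 1:
            raise ValueError("need at least one posterior draw")
        if self.kernel_jitter is not None and self.kernel_jitter <= 0:
            raise ValueError("jitter must be positive")
        if self.latent_prior_scale <= 0:
            raise ValueError("latent_prior_scale must be positive")


@dataclass(frozen=True)
class PosteriorSamples:
    """Post-burn-in latent-function draws plus the fitted-kernel geometry."""

    latent_draws: np.ndarray          # (n_samples, n_train, m)
    training_labels: np.ndarray       # (n_train,) ints 0..m-1
    kernel: KernelMatrix              # the raw training kernel passed to fit
    config: ClassifierConfig
    prior_cov: np.ndarray = field(repr=False)         # S = s (K + jitter I)
    prior_cov_cho: tuple = field(repr=False)          # cho_factor(S)

    @property
    def n_train(self) -> int:
        return self.latent_draws.shape[1]


@dataclass(frozen=True)
class PredictiveDistribution:
    probabilities: np.ndarray         # (n_test, m), rows sum to 1
    subject_ids: tuple[str, ...] = ()


def _truncnorm_above(rng, mu, lower):
    """Sample N(mu, 1) conditioned on being > lower (vectorised, inverse CDF)."""
    lo = ndtr(lower - mu)
    u = lo + rng.random(np.shape(mu)) * (1.0 - lo)
    return mu + ndtri(np.clip(u, _EPS, 1.0 - _EPS))


def _truncnorm_below(rng, mu, upper):
    """Sample N(mu, 1) conditioned on being < upper (vectorised, inverse CDF)."""
    hi = ndtr(upper - mu)
    u = rng.random(np.shape(mu)) * hi
    return mu + ndtri(np.clip(u, _EPS, 1.0 - _EPS))


def fit_classifier(
    K_train: KernelMatrix, labels: Sequence[int], config: ClassifierConfig
) -> PosteriorSamples:
    """Run the auxiliary-variable Gibbs sampler on a training kernel.

    ``labels`` are integer class codes 0..m-1; every class must appear.
    Reproducible from ``config.seed``.
    """
    K = np.asarray(K_train.values, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("training kernel must be square")
    y = np.asarray(labels, dtype=int)
    if y.shape != (n,):
        raise ValueError("labels length must match kernel size")
    m = config.n_classes
    present = set(np.unique(y))
    if not present <= set(range(m)):
        raise ValueError(f"labels outside 0..{m - 1}: {sorted(present)}")
    missing = set(range(m)) - present
    if missing:
        raise ValueError(f"classes absent from training labels: {sorted(missing)}")

    jitter = config.kernel_jitter
    if jitter is None:
        jitter = 1e-6 * max(float(np.mean(np.diag(K))), _EPS)
    S = config.latent_prior_scale * (K + jitter * np.eye(n))
    try:
        S_cho = cho_factor(S, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("kernel is not positive definite after jitter") from exc

    # Posterior update for f | a: mean M a, covariance M, M = S (S + I)^{-1}.
    M = cho_solve(cho_factor(S + np.eye(n), lower=True), S)
    M = 0.5 * (M + M.T)
    L_post = np.linalg.cholesky(M + 1e-12 * np.eye(n))

    rng = np.random.default_rng(config.seed)
    rows = np.arange(n)
    F = np.zeros((n, m))
    A = np.zeros((n, m))
    A[rows, y] = 1.0

    n_iter = config.n_burnin + config.n_samples
    draws = np.empty((config.n_samples, n, m))
    neg_inf = np.full(n, -np.inf)
    for it in range(n_iter):
        # (a) auxiliary variables: one Gibbs scan of the truncated system
        # a_{n, y_n} > a_{n, c} for all c != y_n.
        others = A.copy()
        others[rows, y] = neg_inf
        best_other = others.max(axis=1)
        A[rows, y] = _truncnorm_above(rng, F[rows, y], best_other)
        upper = A[rows, y][:, None]
        cand = _truncnorm_below(rng, F, upper)
        keep = A[rows, y]
        A = cand
        A[rows, y] = keep
        # (b) latent functions: Gaussian conditional, all classes at once.
        F = M @ A + L_post @ rng.standard_normal((n, m))
        if it >= config.n_burnin:
            draws[it - config.n_burnin] = F

    return PosteriorSamples(
        latent_draws=draws,
        training_labels=y,
        kernel=K_train,
        config=config,
        prior_cov=S,
        prior_cov_cho=S_cho,
    )


def predict_probabilities(
    post: PosteriorSamples,
    K_cross: KernelMatrix,
    K_test_diag: np.ndarray,
    n_quad: int = 32,
) -> PredictiveDistribution:
    """Posterior predictive class probabilities for test subjects.

    ``K_cross`` has one row per test subject and one column per training
    subject on the same scale as the training kernel; ``K_test_diag`` carries
    the test self-similarities.  For each posterior draw the conditional mean
    of the test latents is computed per class; the conditional variance
    (shared across classes) is marginalised analytically by inflating the
    probit noise, and the argmax probability is accumulated by Gauss–Hermite
    quadrature over the shared noise variable.  Deterministic given the
    posterior draws.
    """
    Kc = np.asarray(K_cross.values, dtype=float)
    if Kc.ndim != 2 or Kc.shape[1] != post.n_train:
        raise ValueError("cross-kernel columns must match training subjects")
    diag = np.asarray(K_test_diag, dtype=float)
    if diag.shape != (Kc.shape[0],):
        raise ValueError("test diagonal length must match cross-kernel rows")

    cfg = post.config
    s = cfg.latent_prior_scale
    Sc = s * Kc                                      # Cov(f*, f_train)
    beta = cho_solve(post.prior_cov_cho, Sc.T)       # (n_train, n_test)
    var = s * diag - np.einsum("ij,ij->j", Sc.T, beta)
    var = np.clip(var, 0.0, None)
    # The conditional variance is shared across classes, so the Gaussian test
    # latents can be folded into the probit noise: score_c = mu_c + eta_c with
    # eta iid N(0, 1 + var).  P(argmax = c) then reduces to a one-dimensional
    # integral over the shared standardised noise.
    noise_sd = np.sqrt(1.0 + var)                    # (n_test,)

    n_test, m = Kc.shape[0], cfg.n_classes
    # conditional means per draw: (S, n_test, m)
    means = np.einsum("nt,snm->stm", beta, post.latent_draws)

    x, w = hermgauss(n_quad)
    u = np.sqrt(2.0) * x                             # N(0,1) nodes
    wt = w / np.sqrt(np.pi)

    n_draws = means.shape[0]
    probs = np.zeros((n_test, m))
    chunk = max(1, int(2_000_000 // max(1, n_test * m * m * n_quad)))
    for lo in range(0, n_draws, chunk):
        mu = means[lo:lo + chunk] / noise_sd[None, :, None]
        # G[s,t,c,j,k] = Phi(u_k + mu_c - mu_j); diagonal forced to 1
        d = mu[..., :, None] - mu[..., None, :]
        G = ndtr(u[None, None, None, None, :] + d[..., None])
        G[..., np.arange(m), np.arange(m), :] = 1.0
        probs += np.einsum("stck,k->tc", np.prod(G, axis=-2), wt)
    probs /= n_draws
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return PredictiveDistribution(probabilities=probs, subject_ids=K_cross.row_ids)


def assign_class(pred: PredictiveDistribution) -> np.ndarray:
    """Hard labels by row argmax; exact ties resolve to the lowest index."""
    p = pred.probabilities
    hard = np.argmax(p, axis=1)
    ties = (p == p.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if np.any(ties):
        logger.warning(
            "%d probability tie(s) broken toward the lowest class index",
            int(ties.sum()),
        )
    return hard
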