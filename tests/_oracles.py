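"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's sampling code paths: the binary
multinomial-probit predictive is computed by dense Gauss-Hermite quadrature
over the latent *difference* process, which for two classes reduces the
model to a binary probit GP and admits direct numerical integration at
small n.
"""

import itertools

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import ndtr


def binary_probit_predictive(K, labels, K_cross, k_diag, scale, jitter, n_nodes=24):
    """Exact (quadrature) predictive P(class 0) for the two-class model.

    Model: f_0, f_1 ~ N(0, S), S = scale*(K + jitter*I); observed label 0
    iff f_0 + e_0 > f_1 + e_1 with unit-normal noise.  The difference
    g = f_0 - f_1 has prior N(0, 2S) and P(label 0 | g_n) = Phi(g_n/sqrt(2)).
    The posterior over g is integrated on a product Gauss-Hermite grid
    (feasible for n <= ~5), and the test predictive marginalises the
    conditional Gaussian of g* analytically:
    P(y* = 0) = E_post[ Phi(a.g / sqrt(2 + v)) ].
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    y = np.asarray(labels)
    S = scale * (K + jitter * np.eye(n))
    Cg = 2.0 * S
    L = np.linalg.cholesky(Cg)

    x, w = hermgauss(n_nodes)
    nodes = np.sqrt(2.0) * x
    grids = np.meshgrid(*([nodes] * n), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=0)          # (n, n_nodes**n)
    G = L @ Z                                                  # prior samples of g
    logw = np.add.reduce(
        np.meshgrid(*([np.log(w)] * n), indexing="ij")
    ).ravel()

    sign = np.where(y == 0, 1.0, -1.0)
    lik = np.prod(ndtr(sign[:, None] * G / np.sqrt(2.0)), axis=0)
    weights = np.exp(logw) * lik
    weights /= weights.sum()

    Kc = np.atleast_2d(np.asarray(K_cross, dtype=float))
    a = scale * Kc @ np.linalg.solve(S, np.eye(n))             # conditional-mean map
    v = 2.0 * (scale * np.asarray(k_diag) - np.einsum("ij,jk,ik->i", scale * Kc,
                                                      np.linalg.inv(S), scale * Kc))
    v = np.clip(v, 0.0, None)
    mu_star = a @ G                                            # (n_test, n_points)
    p0 = ndtr(mu_star / np.sqrt(2.0 + v)[:, None]) @ weights
    return np.asarray(p0)


def metrics_by_hand(counts):
    """Naive per-cell metric computation for a confusion matrix."""
    C = np.asarray(counts, dtype=float)
    m = C.shape[0]
    sens, pv = [], []
    for i in range(m):
        row = sum(C[i, j] for j in range(m))
        col = sum(C[j, i] for j in range(m))
        sens.append(C[i, i] / row if row else 0.0)
        pv.append(C[i, i] / col if col else 0.0)
    return (
        np.array(sens),
        np.array(pv),
        float(np.mean(sens)),
        float(np.mean(pv)),
    )
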