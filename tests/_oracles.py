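"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written from scratch against the model
definition (direct softmax over category logits; EM with fixed-point
Gauss-Hermite quadrature) and stays free of the package's vectorized
likelihood and MH-RM code paths.
"""

import numpy as np
from scipy.special import logsumexp


def brute_force_probabilities(theta, slopes, item_weights, intercepts):
    """Direct softmax over per-category logits, one scalar loop at a time."""
    K1 = len(intercepts)
    logits = []
    for k in range(K1):
        s = intercepts[k]
        for d in range(len(theta)):
            s += slopes[d] * item_weights[d][k] * theta[d]
        logits.append(s)
    m = max(logits)
    ex = [np.exp(v - m) for v in logits]
    tot = sum(ex)
    return np.array([v / tot for v in ex])


def brute_force_loglik(responses, thetas, slopes, weights, intercepts):
    """Sum of log model probabilities over every (person, item) cell."""
    total = 0.0
    N, I = responses.shape
    for n in range(N):
        for i in range(I):
            p = brute_force_probabilities(
                thetas[n], slopes[i], weights[i], intercepts[i]
            )
            total += np.log(p[responses[n, i]])
    return total


def em_fit_1d(y, S, n_quad=41, max_iter=500, tol=1e-9):
    """Marginal ML for a unidimensional model by EM with GH quadrature.

    ``y``: N x I integer responses; ``S``: I x 1 x (K+1) scoring weights.
    Returns (slopes, intercepts, iterations).  The latent trait is standard
    normal; intercept of category 0 fixed at 0.
    """
    N, I = y.shape
    K1 = S.shape[2]
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = np.sqrt(2.0) * z
    logw = np.log(w) - 0.5 * np.log(np.pi)
    a = np.full(I, 0.5)
    counts = np.stack([(y == k).sum(0) for k in range(K1)], 1).astype(float)
    g = np.log(counts + 0.5)
    g = g - g[:, :1]
    for it in range(max_iter):
        logits = a[None, :, None] * S[None, :, 0, :] * nodes[:, None, None] + g[None]
        lp = logits - logsumexp(logits, axis=2, keepdims=True)
        lpg = np.take_along_axis(lp[None], y[:, None, :, None], axis=3)[:, :, :, 0]
        ll = lpg.sum(2) + logw[None, :]
        post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))  # N x Q
        r = np.einsum("nq,nik->qik", post, np.eye(K1)[y])
        nq = post.sum(0)
        a_new, g_new = a.copy(), g.copy()
        for i in range(I):
            ai, gi = a[i], g[i].copy()
            for _ in range(50):
                lo = ai * S[i, 0][None, :] * nodes[:, None] + gi[None]
                p = np.exp(lo - logsumexp(lo, axis=1, keepdims=True))
                Ek = nq[:, None] * p
                x = S[i, 0][None, :] * nodes[:, None]
                ga = ((r[:, i, :] - Ek) * x).sum()
                gg = (r[:, i, :] - Ek).sum(0)[1:]
                grad = np.r_[ga, gg]
                m1 = (p * x).sum(1)
                Iaa = (nq * ((p * x * x).sum(1) - m1**2)).sum()
                Iag = (nq[:, None] * (p * x - m1[:, None] * p))[:, 1:].sum(0)
                Igg = np.diag(Ek.sum(0)[1:]) - np.einsum(
                    "qk,qm->km", p[:, 1:] * nq[:, None], p[:, 1:]
                )
                H = np.zeros((K1, K1))
                H[0, 0] = Iaa
                H[0, 1:] = Iag
                H[1:, 0] = Iag
                H[1:, 1:] = Igg
                step = np.linalg.solve(H + 1e-10 * np.eye(K1), grad)
                ai += step[0]
                gi[1:] += step[1:]
                if np.abs(step).max() < 1e-11:
                    break
            a_new[i], g_new[i] = ai, gi
        change = max(np.abs(a_new - a).max(), np.abs(g_new - g).max())
        a, g = a_new, g_new
        if change < tol:
            break
    return a, g, it
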