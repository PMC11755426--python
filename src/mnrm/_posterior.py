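"""Per-person posterior machinery shared by scoring and marginal likelihoods.

The log posterior f(theta) = log p(Y_n | theta) + log phi(theta; 0, Sigma)
is strictly concave in theta (a logsumexp of linear functions plus a
Gaussian log-density), so damped Newton ascent from the prior mode finds
the unique maximizer for every person; all persons are iterated in one
vectorized sweep.
"""

from __future__ import annotations

import numpy as np

from .model import (
    ItemParameters,
    LatentSpec,
    ResponseMatrix,
    effective_weights,
    response_logits,
)
from .weights import ScoringWeightSet


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    p = np.exp(logits - m)
    p /= p.sum(axis=-1, keepdims=True)
    return p


def _f_grad_hess(responses, params, weights, latent, theta, prec):
    """Value, gradient and Hessian of f at theta (N x D), all persons at once."""
    W = effective_weights(params, weights)  # I x D x K1
    logits = response_logits(theta, params, weights)  # N x I x K1
    m = logits.max(axis=-1, keepdims=True)
    sumexp = np.exp(logits - m).sum(axis=-1)
    lse = m[:, :, 0] + np.log(sumexp)
    y = responses.data
    chosen = np.take_along_axis(logits, y[:, :, None], axis=-1)[:, :, 0]
    p = _softmax(logits)

    # value
    quad = np.einsum("nd,de,ne->n", theta, prec, theta)
    logdet_term = 0.5 * np.linalg.slogdet(prec)[1]
    D = theta.shape[1]
    f = (chosen - lse).sum(axis=1) - 0.5 * quad + logdet_term - 0.5 * D * np.log(2 * np.pi)

    # gradient: sum_i (w_{i,:,y} - E_p w) - prec theta
    Wt = W.transpose(0, 2, 1)  # I x K1 x D
    obs = Wt[np.arange(len(params.slopes))[None, :], y]  # N x I x D
    exp_w = np.einsum("nik,idk->nd", p, W, optimize=True)
    grad = obs.sum(axis=1) - exp_w - theta @ prec

    # Hessian: -sum_i cov_p(w) - prec
    m2 = np.einsum("nik,idk,iek->nde", p, W, W, optimize=True)
    m1 = np.einsum("nik,idk->nid", p, W, optimize=True)
    h = -(m2 - np.einsum("nid,nie->nde", m1, m1)) - prec
    return f, grad, h


def posterior_modes(
    responses: ResponseMatrix,
    params: ItemParameters,
    weights: ScoringWeightSet,
    latent: LatentSpec,
    max_iter: int = 60,
    tol: float = 1e-9,
    start: np.ndarray | None = None,
):
    """Posterior mode, Hessian of f at the mode, and convergence flags.

    Returns ``(modes (N, D), hessians (N, D, D), converged (N,))``.
    """
    N = responses.n_persons
    D = latent.n_dim
    prec = np.linalg.inv(latent.corr)
    theta = np.zeros((N, D)) if start is None else np.array(start, dtype=float)
    f, grad, h = _f_grad_hess(responses, params, weights, latent, theta, prec)
    converged = np.zeros(N, dtype=bool)
    for _ in range(max_iter):
        step = np.linalg.solve(-h, grad[:, :, None])[:, :, 0]
        alpha = np.ones((N, 1))
        # vectorized backtracking: halve steps for persons whose f decreased
        for _bt in range(25):
            cand = theta + alpha * step
            f_new, grad_new, h_new = _f_grad_hess(
                responses, params, weights, latent, cand, prec
            )
            bad = f_new < f - 1e-12
            if not bad.any():
                break
            alpha[bad] *= 0.5
        theta, f, grad, h = cand, f_new, grad_new, h_new
        converged = np.abs(grad).max(axis=1) < tol
        if converged.all():
            break
    return theta, h, converged


def laplace_logliks(responses, params, weights, latent, modes, hess):
    """Per-person Laplace approximation of log integral exp(f) dtheta."""
    prec = np.linalg.inv(latent.corr)
    f, _, _ = _f_grad_hess(responses, params, weights, latent, modes, prec)
    D = modes.shape[1]
    _, logdet = np.linalg.slogdet(-hess)
    return f + 0.5 * D * np.log(2 * np.pi) - 0.5 * logdet
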