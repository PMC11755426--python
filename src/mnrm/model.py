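"""The multidimensional nominal response model (MNRM).

The probability that person n chooses category k of item i is a
multinomial logit over the K+1 categories,

    p(Y_ni = k | theta_n) = exp(sum_d alpha_id s_idk theta_nd + gamma_ik)
                            / sum_m exp(sum_d alpha_id s_idm theta_nd + gamma_im),

where alpha_id are item slopes, s_idk fixed scoring weights, gamma_ik
item-category intercepts (gamma_i0 = 0 for identification), and theta_n the
person's levels on the D latent dimensions, distributed multivariate normal
with zero means and unit variances (a correlation matrix Sigma).

This module evaluates the model, samples responses from it, and computes
complete-data and marginal log-likelihoods.  Marginal likelihoods integrate
the latent vector out numerically: a Laplace approximation at the
per-person posterior mode (default; deterministic and usable at D = 8),
adaptive Gauss-Hermite quadrature (D <= 3), or importance sampling seeded
from the Laplace proposal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .errors import CapabilityError, NumericError, ShapeError
from .weights import ScoringWeightSet


@dataclass(frozen=True)
class ItemParameters:
    """Per-item slope vectors (I x D) and category intercepts (I x (K+1)).

    The first-category intercept is fixed to 0 for every item.
    """

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "slopes", np.asarray(self.slopes, dtype=float))
        object.__setattr__(
            self, "intercepts", np.asarray(self.intercepts, dtype=float)
        )
        if self.slopes.ndim != 2 or self.intercepts.ndim != 2:
            raise ShapeError("slopes and intercepts must be 2-d arrays")
        if self.slopes.shape[0] != self.intercepts.shape[0]:
            raise ShapeError("slopes and intercepts disagree on item count")
        if not (np.all(np.isfinite(self.slopes)) and np.all(np.isfinite(self.intercepts))):
            raise NumericError("item parameters contain non-finite values")
        if np.any(self.intercepts[:, 0] != 0):
            raise ShapeError("gamma_i0 must be 0 for every item")

    @property
    def n_items(self) -> int:
        return self.slopes.shape[0]

    @property
    def n_dim(self) -> int:
        return self.slopes.shape[1]

    @property
    def n_categories(self) -> int:
        return self.intercepts.shape[1]


@dataclass(frozen=True)
class LatentSpec:
    """Latent dimension roles and their correlation matrix.

    Means are fixed at zero and variances at one (identification), so the
    covariance matrix is a correlation matrix.
    """

    roles: tuple[str, ...]
    corr: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "roles", tuple(self.roles))
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        D = len(self.roles)
        if corr.shape != (D, D):
            raise ShapeError(f"correlation matrix must be {D}x{D}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ShapeError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-9):
            raise ShapeError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 1e-10:
            raise ShapeError("correlation matrix must be positive definite")

    @property
    def n_dim(self) -> int:
        return len(self.roles)

    @property
    def mean(self) -> np.ndarray:
        return np.zeros(self.n_dim)


@dataclass(frozen=True)
class ResponseMatrix:
    """N x I integer responses in {0..K} with the item-to-trait assignment."""

    data: np.ndarray
    items: tuple[str, ...]
    item_traits: np.ndarray = field(repr=False)
    n_categories: int = 0

    def __post_init__(self):
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise ShapeError("responses must be integers")
            data = data.astype(np.int64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "item_traits", np.asarray(self.item_traits, dtype=int))
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ShapeError("responses must be a non-empty N x I matrix")
        if data.shape[1] != len(self.items):
            raise ShapeError("response columns disagree with item list")
        if self.item_traits.shape != (len(self.items),):
            raise ShapeError("item_traits must have one entry per item")
        K1 = self.n_categories
        if K1 < 2:
            raise ShapeError("need at least two response categories")
        if data.min() < 0 or data.max() >= K1:
            raise ShapeError(
                f"responses must lie in 0..{K1 - 1}, found range "
                f"[{data.min()}, {data.max()}]"
            )

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Vectorized likelihood machinery
# ---------------------------------------------------------------------------

def effective_weights(params: ItemParameters, weights: ScoringWeightSet) -> np.ndarray:
    """Slope-scaled scoring weights ``alpha_id * s_idk`` as an (I, D, K+1) array."""
    if params.slopes.shape != (weights.n_items, weights.n_dim):
        raise ShapeError(
            f"slopes {params.slopes.shape} inconsistent with weight set "
            f"({weights.n_items}, {weights.n_dim})"
        )
    return params.slopes[:, :, None] * weights.weights


def response_logits(
    theta: np.ndarray, params: ItemParameters, weights: ScoringWeightSet
) -> np.ndarray:
    """Category logits for every (person, item): shape (..., I, K+1).

    ``theta`` may be (D,), (N, D) or (N, Q, D); the logit array gains the
    matching leading axes.
    """
    theta = np.asarray(theta, dtype=float)
    W = effective_weights(params, weights)
    logits = np.einsum("...d,idk->...ik", theta, W, optimize=True)
    return logits + params.intercepts


def category_probabilities(
    theta: np.ndarray,
    slopes: np.ndarray,
    item_weights: np.ndarray,
    intercepts: np.ndarray,
) -> np.ndarray:
    """Category probabilities of a single item for one person.

    Evaluates the multinomial logit with logits ``sum_d alpha_d s_dk
    theta_d + gamma_k``, max-shifted before exponentiation for numerical
    stability.  Sums to 1 within 1e-12 and every entry is strictly
    positive.
    """
    theta = np.asarray(theta, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    item_weights = np.asarray(item_weights, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    if theta.shape != slopes.shape:
        raise ShapeError(f"theta {theta.shape} vs slopes {slopes.shape}")
    if item_weights.shape != (theta.shape[0], intercepts.shape[0]):
        raise ShapeError(
            f"weights {item_weights.shape} inconsistent with D={theta.shape[0]}, "
            f"K+1={intercepts.shape[0]}"
        )
    for a in (theta, slopes, item_weights, intercepts):
        if not np.all(np.isfinite(a)):
            raise NumericError("non-finite input to category_probabilities")
    logits = (slopes * theta) @ item_weights + intercepts
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def sample_response(
    theta: np.ndarray,
    slopes: np.ndarray,
    item_weights: np.ndarray,
    intercepts: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Draw one response category by inverse CDF on the category probabilities."""
    p = category_probabilities(theta, slopes, item_weights, intercepts)
    u = rng.random()
    return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, len(p) - 1))


def simulate_responses(
    theta: np.ndarray,
    params: ItemParameters,
    weights: ScoringWeightSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample an N x I response matrix given person parameters.

    Uses one uniform per (person, item) cell in row-major order, so the
    draw is reproducible under a fixed stream regardless of how
    probabilities are computed.
    """
    logits = response_logits(theta, params, weights)
    logits -= logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(size=cdf.shape[:-1] + (1,))
    draws = (u > cdf).sum(axis=-1)
    return np.minimum(draws, p.shape[-1] - 1).astype(np.int64)


def person_logliks(
    responses: ResponseMatrix,
    theta: np.ndarray,
    params: ItemParameters,
    weights: ScoringWeightSet,
) -> np.ndarray:
    """log p(Y_n | theta_n) summed over items; theta (N, D) or (N, Q, D).

    With a (N, Q, D) theta batch the result is (N, Q): each person's
    responses evaluated at their Q candidate latent vectors.
    """
    _check_alignment(responses, params, weights)
    logits = response_logits(theta, params, weights)
    lse = logsumexp(logits, axis=-1)
    y = responses.data
    if logits.ndim == 3:
        chosen = np.take_along_axis(logits, y[:, :, None], axis=-1)[:, :, 0]
        return (chosen - lse).sum(axis=-1)
    chosen = np.take_along_axis(
        logits, y[:, None, :, None], axis=-1
    )[:, :, :, 0]
    return (chosen - lse).sum(axis=-1)


def complete_data_loglik(
    responses: ResponseMatrix,
    thetas: np.ndarray,
    params: ItemParameters,
    weights: ScoringWeightSet,
) -> float:
    """Sum over persons and items of log p(Y_ni | theta_n)."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (responses.n_persons, params.n_dim):
        raise ShapeError(
            f"thetas must be ({responses.n_persons}, {params.n_dim}), "
            f"got {thetas.shape}"
        )
    return float(person_logliks(responses, thetas, params, weights).sum())


def _check_alignment(
    responses: ResponseMatrix, params: ItemParameters, weights: ScoringWeightSet
) -> None:
    if responses.n_items != params.n_items or responses.n_items != weights.n_items:
        raise ShapeError("responses, parameters and weights disagree on items")
    if responses.n_categories != weights.n_categories:
        raise ShapeError("responses and weights disagree on category count")
    if params.n_categories != weights.n_categories:
        raise ShapeError("parameters and weights disagree on category count")
    if params.n_dim != weights.n_dim:
        raise ShapeError("parameters and weights disagree on dimension count")


# ---------------------------------------------------------------------------
# Marginal log-likelihood
# ---------------------------------------------------------------------------

def marginal_loglik(
    responses: ResponseMatrix,
    params: ItemParameters,
    weights: ScoringWeightSet,
    latent: LatentSpec,
    method: str = "laplace",
    mc_size: int = 256,
    seed: int | None = None,
    n_nodes: int = 21,
) -> float:
    """Approximate sum_n log integral p(Y_n | theta) phi(theta; 0, Sigma) dtheta.

    ``method`` is one of ``laplace`` (default), ``quadrature`` (adaptive
    Gauss-Hermite, D <= 3, ``n_nodes`` per dimension), ``importance``
    (``mc_size`` draws per person from a normal proposal centred at the
    posterior mode with curvature-matched covariance; seeded, hence
    reproducible), or ``montecarlo`` (plain Monte Carlo with ``mc_size``
    antithetic draws from the latent prior, shared across persons — the
    estimator common IRT software reports for stochastically fitted
    models; noisy and biased low for sharp posteriors, provided for
    comparability).  Model comparisons must use one method and seed for
    both fits.
    """
    from ._posterior import laplace_logliks, posterior_modes

    _check_alignment(responses, params, weights)
    if latent.n_dim != params.n_dim:
        raise ShapeError("latent spec and parameters disagree on dimensions")
    if method == "quadrature" and latent.n_dim > 3:
        raise CapabilityError(
            f"product quadrature limited to D <= 3, model has D = {latent.n_dim}"
        )
    if method == "montecarlo":
        return _prior_mc_loglik(responses, params, weights, latent, mc_size, seed)

    modes, hess, _ = posterior_modes(responses, params, weights, latent)
    if method == "laplace":
        return float(laplace_logliks(responses, params, weights, latent, modes, hess).sum())
    if method == "quadrature":
        return _quadrature_loglik(
            responses, params, weights, latent, modes, hess, n_nodes
        )
    if method == "importance":
        return _importance_loglik(
            responses, params, weights, latent, modes, hess, mc_size, seed
        )
    raise CapabilityError(f"unknown marginal-likelihood method {method!r}")


def _log_prior(theta: np.ndarray, latent: LatentSpec) -> np.ndarray:
    return multivariate_normal.logpdf(theta, mean=latent.mean, cov=latent.corr)


def _joint_logpost(responses, params, weights, latent, theta):
    """f(theta) = log p(Y | theta) + log phi(theta); theta (N, Q, D) -> (N, Q)."""
    return person_logliks(responses, theta, params, weights) + _log_prior(theta, latent)


def _quadrature_loglik(responses, params, weights, latent, modes, hess, n_nodes):
    D = latent.n_dim
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([nodes] * D), indexing="ij")
    z = np.stack([g.ravel() for g in grids], axis=-1)  # Q x D
    logw = np.log(wts)
    lg = np.meshgrid(*([logw] * D), indexing="ij")
    logw_q = np.add.reduce([g.ravel() for g in lg])  # Q

    cov = np.linalg.inv(-hess)  # N x D x D
    L = np.linalg.cholesky(cov)
    theta = modes[:, None, :] + np.sqrt(2.0) * np.einsum("nde,qe->nqd", L, z)
    f = _joint_logpost(responses, params, weights, latent, theta)
    _, logdetL = np.linalg.slogdet(L)
    per_person = logsumexp(
        f + logw_q[None, :] + (z**2).sum(axis=1)[None, :], axis=1
    ) + 0.5 * D * np.log(2.0) + logdetL
    return float(per_person.sum())


def _prior_mc_loglik(responses, params, weights, latent, mc_size, seed):
    if mc_size < 2:
        raise CapabilityError("Monte Carlo integration needs mc_size >= 2")
    rng = np.random.default_rng(seed)
    D = latent.n_dim
    z = rng.standard_normal(((mc_size + 1) // 2, D))
    z = np.concatenate([z, -z], axis=0)[:mc_size]
    theta = z @ np.linalg.cholesky(latent.corr).T
    logits = response_logits(theta, params, weights)  # Q x I x K1
    lp = logits - logsumexp(logits, axis=-1, keepdims=True)
    lp_t = lp.transpose(1, 2, 0)  # I x K1 x Q
    y = responses.data
    ll = np.zeros((y.shape[0], theta.shape[0]))
    for i in range(y.shape[1]):
        ll += lp_t[i, y[:, i], :]
    return float((logsumexp(ll, axis=1) - np.log(theta.shape[0])).sum())


def _importance_loglik(responses, params, weights, latent, modes, hess, mc_size, seed):
    if mc_size < 2:
        raise CapabilityError("importance sampling needs mc_size >= 2")
    rng = np.random.default_rng(seed)
    N, D = modes.shape
    cov = np.linalg.inv(-hess)
    L = np.linalg.cholesky(cov)
    # antithetic standard-normal draws shared across persons
    half = (mc_size + 1) // 2
    z = rng.standard_normal(size=(half, D))
    z = np.concatenate([z, -z], axis=0)[:mc_size]
    theta = modes[:, None, :] + np.einsum("nde,qe->nqd", L, z)
    f = _joint_logpost(responses, params, weights, latent, theta)
    _, logdetL = np.linalg.slogdet(L)
    # log q(theta) under N(mode, L L')
    quad = (z**2).sum(axis=1)
    logq = -0.5 * quad[None, :] - 0.5 * D * np.log(2 * np.pi) - logdetL[:, None]
    per_person = logsumexp(f - logq, axis=1) - np.log(mc_size)
    return float(per_person.sum())
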