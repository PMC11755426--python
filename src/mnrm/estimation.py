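"""Stochastic-approximation marginal maximum likelihood for the MNRM.

The fitter follows the Metropolis-Hastings Robbins-Monro (MH-RM) recipe:
each cycle imputes the latent person vectors with a component-wise
random-walk Metropolis sweep given the current item parameters, then moves
the item parameters along an approximate Newton direction of the
complete-data log-likelihood, with a Robbins-Monro gain schedule and a
running (gain-weighted) accumulation of the complete-data Fisher
information.  The latent correlation matrix is updated from the imputed
second moments and renormalized to unit variances each cycle.

Identification follows the usual constraints: latent means 0, variances 1,
and the first-category intercept 0 for every item.

Person scores are maximum a-posteriori (MAP) estimates; scoring a fresh
sample with fixed item parameters (e.g., applying a high-stakes calibration
to a low-stakes sample) is first-class via :func:`map_scores`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._kernels import mstep_kernel
from ._posterior import posterior_modes
from .errors import ConvergenceError, NestingError, ShapeError
from .model import ItemParameters, LatentSpec, ResponseMatrix
from .weights import ScoringWeightSet


# ---------------------------------------------------------------------------
# Options and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Tuning constants of the MH-RM fitter.

    ``burnin`` cycles run with constant gain 1; afterwards the gain decays
    as ``t ** -gain_decay``.  From ``min_stage2`` decay cycles onward the
    parameter trajectory is Polyak-Ruppert averaged; convergence is
    declared when the largest absolute change of the running averages
    stays below ``tol`` over a sliding window of ``window`` cycles, with
    at least ``min_avg`` averaged cycles.  ``max_cycles`` caps the total.
    The Metropolis proposal scale per dimension adapts toward the
    acceptance band ``accept_target`` during burn-in and is frozen
    afterwards.
    """

    burnin: int = 200
    max_cycles: int = 2000
    min_stage2: int = 100
    min_avg: int = 100
    gain_decay: float = 0.75
    tol: float = 1e-3
    window: int = 3
    mh_sweeps: int = 1
    info_every: int = 1
    accept_target: tuple[float, float] = (0.23, 0.45)
    max_step: float = 1.0
    ll_method: str = "laplace"
    ll_mc_size: int = 256
    ll_nodes: int = 21
    ll_seed: int | None = None
    require_convergence: bool = True


@dataclass(frozen=True)
class FitResult:
    """Point estimates and bookkeeping from one MH-RM fit."""

    params: ItemParameters
    latent: LatentSpec
    weights: ScoringWeightSet = field(repr=False)
    loglik: float
    ll_method: str
    n_params: int
    constraint_mode: str
    seed: int
    n_persons: int
    trace: np.ndarray = field(repr=False)
    n_cycles: int
    converged: bool
    ll_seed: int | None = None
    ll_mc_size: int = 0

    def __post_init__(self):
        if len(self.trace) == 0:
            raise ShapeError("convergence trace must be non-empty")


@dataclass(frozen=True)
class PersonScores:
    """N x D MAP estimates with per-person convergence flags."""

    scores: np.ndarray
    converged: np.ndarray
    roles: tuple[str, ...]

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class LRTest:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ModelComparison:
    """Fit statistics and adjacent-pair LR tests for a nested model chain."""

    names: tuple[str, ...]
    loglik: tuple[float, ...]
    n_params: tuple[int, ...]
    aic: tuple[float, ...]
    bic: tuple[float, ...]
    lr_tests: tuple[LRTest | None, ...]  # entry j tests fits[j-1] vs fits[j]
    selected: dict[str, int]

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, name in enumerate(self.names):
            lr = self.lr_tests[j]
            rows.append(
                {
                    "model": name,
                    "loglik": self.loglik[j],
                    "n_params": self.n_params[j],
                    "AIC": self.aic[j],
                    "BIC": self.bic[j],
                    "LR_stat": lr.statistic if lr else np.nan,
                    "LR_df": lr.df if lr else np.nan,
                    "LR_p": lr.p_value if lr else np.nan,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter counting and criteria
# ---------------------------------------------------------------------------

def count_free_parameters(
    n_items: int,
    n_categories: int,
    n_dim: int,
    constraint_mode: str = "free",
    loadings_per_item: int | None = None,
) -> int:
    """Number of free parameters of an MNRM configuration.

    Free slopes contribute one parameter per loading dimension per item;
    equality-constrained slopes one per dimension.  Intercepts contribute
    K per item (first category fixed), and the latent correlation matrix
    D(D-1)/2.
    """
    if constraint_mode not in ("free", "equal"):
        raise ShapeError(f"unknown constraint mode {constraint_mode!r}")
    if constraint_mode == "free":
        if loadings_per_item is None:
            raise ShapeError("free-slope counting needs loadings_per_item")
        slopes = n_items * loadings_per_item
    else:
        slopes = n_dim
    intercepts = n_items * (n_categories - 1)
    covariances = n_dim * (n_dim - 1) // 2
    return slopes + intercepts + covariances


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """AIC = -2 LL + 2 p and BIC = -2 LL + p ln N."""
    aic = -2.0 * fit.loglik + 2.0 * fit.n_params
    bic = -2.0 * fit.loglik + fit.n_params * np.log(fit.n_persons)
    return float(aic), float(bic)


def lr_test(restricted: FitResult, full: FitResult) -> LRTest:
    """Likelihood-ratio test of a nested pair, chi-square reference.

    The statistic is floored at zero; both fits must carry log-likelihoods
    from the same method (and seed, for stochastic methods).
    """
    df = full.n_params - restricted.n_params
    if df <= 0:
        raise NestingError(
            f"full model must have more parameters ({full.n_params} vs "
            f"{restricted.n_params})"
        )
    if restricted.ll_method != full.ll_method or restricted.ll_seed != full.ll_seed:
        raise NestingError(
            "log-likelihoods must come from the same method and seed "
            f"({restricted.ll_method}/{restricted.ll_seed} vs "
            f"{full.ll_method}/{full.ll_seed})"
        )
    stat = max(0.0, 2.0 * (full.loglik - restricted.loglik))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTest(statistic=float(stat), df=int(df), p_value=p)


def select_model(
    fits: list[FitResult], criterion: str, alpha: float = 0.05
) -> int:
    """Index of the selected model under AIC, BIC, or an LR step-up chain.

    ``lr`` walks the nesting chain and keeps the largest model whose
    addition is significant at ``alpha`` against its predecessor, stopping
    at the first non-significant step.
    """
    if not fits:
        raise ShapeError("empty candidate list")
    if criterion == "aic":
        return int(np.argmin([information_criteria(f)[0] for f in fits]))
    if criterion == "bic":
        return int(np.argmin([information_criteria(f)[1] for f in fits]))
    if criterion in ("lr", "lr_chain", "lr_chain_alpha"):
        selected = 0
        for j in range(1, len(fits)):
            if lr_test(fits[j - 1], fits[j]).p_value < alpha:
                selected = j
            else:
                break
        return selected
    raise ShapeError(f"unknown criterion {criterion!r}")


def compare_models(
    fits: list[FitResult],
    names: list[str] | None = None,
    alpha: float = 0.05,
) -> ModelComparison:
    """Fit-statistic table plus adjacent-pair LR tests for a nested chain."""
    if names is None:
        names = [f"model{j}" for j in range(len(fits))]
    lr_tests: list[LRTest | None] = [None]
    for j in range(1, len(fits)):
        lr_tests.append(lr_test(fits[j - 1], fits[j]))
    ic = [information_criteria(f) for f in fits]
    selected = {
        "lr": select_model(fits, "lr", alpha),
        "aic": select_model(fits, "aic"),
        "bic": select_model(fits, "bic"),
    }
    return ModelComparison(
        names=tuple(names),
        loglik=tuple(f.loglik for f in fits),
        n_params=tuple(f.n_params for f in fits),
        aic=tuple(a for a, _ in ic),
        bic=tuple(b for _, b in ic),
        lr_tests=tuple(lr_tests),
        selected=selected,
    )


# ---------------------------------------------------------------------------
# MAP scoring
# ---------------------------------------------------------------------------

def map_scores(
    responses: ResponseMatrix,
    fit: FitResult | ItemParameters,
    weights: ScoringWeightSet | None = None,
    latent: LatentSpec | None = None,
) -> PersonScores:
    """MAP person scores: per-person maximizer of log p(Y | theta) + log prior.

    Accepts a :class:`FitResult` (which carries parameters, weights and
    latent correlations — this is how a new sample is scored on a fixed
    calibration) or explicit parameter pieces.  Optimizer failures flag
    the person rather than aborting.
    """
    if isinstance(fit, FitResult):
        params, weights, latent = fit.params, fit.weights, fit.latent
    else:
        params = fit
        if weights is None or latent is None:
            raise ShapeError("explicit parameters need weights and latent spec")
    modes, _, converged = posterior_modes(responses, params, weights, latent)
    return PersonScores(scores=modes, converged=converged, roles=latent.roles)


# ---------------------------------------------------------------------------
# The MH-RM fitter
# ---------------------------------------------------------------------------

def _cov2corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


class _MHState:
    """Persistent component-wise Metropolis chain over person parameters.

    Exploits loading sparsity: a proposal on a trait dimension touches only
    that trait's items, so the per-sweep cost is roughly (n_styles + 1)
    full-likelihood evaluations rather than D.  The heavy loop is the
    compiled :func:`mnrm._kernels.sweep_kernel`; all randomness comes from
    the owning generator, so runs are reproducible.
    """

    def __init__(self, responses, weights, n_dim, rng):
        self.rng = rng
        self.y = responses.data
        N, D = responses.n_persons, n_dim
        self.theta = np.zeros((N, D))
        self.scales = np.full(D, 1.0)
        mask = weights.loading_mask()
        items_of_dim = [np.flatnonzero(mask[:, d]) for d in range(D)]
        self.item_idx = np.concatenate(items_of_dim).astype(np.int64)
        self.item_off = np.cumsum([0] + [len(ix) for ix in items_of_dim]).astype(np.int64)
        self.accept = np.zeros(D)

    def run(self, Wt, gamma, prec, n_sweeps, adapt, accept_target=(0.23, 0.45)):
        """Run sweeps and return current logits and log-normalizers.

        The returned arrays reflect the post-sweep latent state, so the
        caller's M-step can form category probabilities without another
        logit evaluation.
        """
        from ._kernels import sweep_kernel

        N, D = self.theta.shape
        I = Wt.shape[0]
        y = self.y
        logits = np.einsum("nd,idk->nik", self.theta, Wt, optimize=True) + gamma
        m = logits.max(axis=-1, keepdims=True)
        lse = m[:, :, 0] + np.log(np.exp(logits - m).sum(axis=-1))
        WtY = Wt.transpose(0, 2, 1)[np.arange(I)[None, :], y]  # N x I x D
        theta_prec = self.theta @ prec
        target = 0.5 * (accept_target[0] + accept_target[1])
        for _ in range(n_sweeps):
            deltas = self.scales[None, :] * self.rng.standard_normal((N, D))
            logu = np.log(self.rng.random((N, D)))
            sweep_kernel(
                self.theta, logits, lse, theta_prec, Wt, WtY,
                np.ascontiguousarray(prec), self.item_idx, self.item_off,
                deltas, logu, self.accept,
            )
            if adapt:
                self.scales *= np.exp(0.3 * (self.accept - target))
                np.clip(self.scales, 0.05, 5.0, out=self.scales)
        return logits, lse


def fit_mnrm(
    responses: ResponseMatrix,
    weights: ScoringWeightSet,
    constraint_mode: str = "free",
    options: FitOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the MNRM by MH-RM stochastic approximation.

    Returns point estimates of slopes, intercepts and the latent
    correlation matrix, with the marginal log-likelihood evaluated at the
    estimates using ``options.ll_method``.  Reproducible for a fixed seed.
    With ``constraint_mode='equal'`` all items within a dimension share one
    slope.
    """
    opts = options or FitOptions()
    if constraint_mode not in ("free", "equal"):
        raise ShapeError(f"unknown constraint mode {constraint_mode!r}")
    if responses.n_items != weights.n_items:
        raise ShapeError("responses and weights disagree on items")
    if responses.n_categories != weights.n_categories:
        raise ShapeError("responses and weights disagree on categories")

    N, I = responses.n_persons, responses.n_items
    D, K1 = weights.n_dim, weights.n_categories
    S = weights.weights
    mask = weights.loading_mask()
    n_load = mask.sum(axis=1)
    if not np.all(n_load == n_load[0]):
        raise ShapeError("items must load on the same number of dimensions")
    L = int(n_load[0])
    active_idx = np.argsort(~mask, axis=1, kind="stable")[:, :L]
    active_idx.sort(axis=1)
    S_act = np.take_along_axis(S, active_idx[:, :, None], axis=1)  # I x L x K1

    # degenerate categories: never-observed cells get a pinned intercept
    counts = np.zeros((I, K1))
    for k in range(K1):
        counts[:, k] = (responses.data == k).sum(axis=0)
    pinned = counts == 0  # I x K1
    if pinned.any():
        warnings.warn(
            f"{int(pinned.sum())} item categories never observed; their "
            "intercepts are pinned to -30",
            stacklevel=2,
        )

    ss = np.random.SeedSequence(seed)
    mh_ss, ll_ss = ss.spawn(2)
    rng = np.random.default_rng(mh_ss)

    # initial values: slopes mid-range, intercepts from marginal frequencies
    if constraint_mode == "free":
        alpha_act = np.full((I, L), 0.5)
    else:
        alpha_shared = np.full(D, 0.5)
    gamma = np.log(counts + 0.5)
    gamma = gamma - gamma[:, :1]
    gamma[:, 0] = 0.0
    gamma[pinned] = -30.0
    gamma[:, 0] = 0.0
    Scov = np.eye(D)
    corr = np.eye(D)

    chain = _MHState(responses, weights, D, rng)
    y = responses.data
    onehot = np.zeros((N, I, K1))
    onehot[np.arange(N)[:, None], np.arange(I)[None, :], y] = 1.0

    P_int = K1 - 1  # free intercepts per item
    n_par = L + P_int
    Gamma = None  # accumulated info, free mode: I x n_par x n_par
    Gamma_a = None  # equal mode slope block D x D
    Gamma_g = None  # equal mode intercept blocks I x K x K
    ridge = 1e-8 * N + 1e-10

    trace: list[float] = []
    converged = False
    n_cycles = 0
    int_pin = pinned[:, 1:]  # I x K mask of pinned free intercepts
    n_avg = 0
    avg_alpha = avg_gamma = avg_scov = None

    for cycle in range(1, opts.max_cycles + 1):
        n_cycles = cycle
        stage2_t = cycle - opts.burnin
        gain = 1.0 if stage2_t <= 0 else float(stage2_t) ** (-opts.gain_decay)

        # --- imputation step -------------------------------------------
        if constraint_mode == "free":
            alpha_full = np.zeros((I, D))
            np.put_along_axis(alpha_full, active_idx, alpha_act, axis=1)
        else:
            alpha_full = np.where(mask, alpha_shared[None, :], 0.0)
        Wt = alpha_full[:, :, None] * S
        prec = np.linalg.inv(corr)
        logits, lse = chain.run(
            Wt, gamma, prec, opts.mh_sweeps, adapt=stage2_t <= 0,
            accept_target=opts.accept_target,
        )
        theta = chain.theta

        # --- approximation step ----------------------------------------
        P = np.exp(logits - lse[:, :, None])

        if constraint_mode == "free":
            th_act = np.ascontiguousarray(theta[:, active_idx])  # N x I x L
            do_info = Gamma is None or (cycle % opts.info_every == 0)
            if Gamma is None:
                Gamma = np.zeros((I, n_par, n_par))
                info = np.zeros((I, n_par, n_par))
                grad = np.zeros((I, n_par))
                first_info = True
            else:
                first_info = False
            mstep_kernel(P, y, th_act, S_act, grad, info, do_info)
            grad[:, L:][int_pin] = 0.0
            if do_info:
                # pinned intercepts: freeze by identity rows
                for i, k in zip(*np.nonzero(int_pin)):
                    info[i, L + k, :] = 0.0
                    info[i, :, L + k] = 0.0
                    info[i, L + k, L + k] = 1.0
                if first_info:
                    Gamma[:] = info
                else:
                    Gamma += gain * (info - Gamma)

            A = Gamma + ridge * np.eye(n_par)
            delta = np.linalg.solve(A, grad[:, :, None])[:, :, 0]
            step = np.clip(gain * delta, -opts.max_step, opts.max_step)
            alpha_act = alpha_act + step[:, :L]
            gamma[:, 1:] = gamma[:, 1:] + step[:, L:]
            gamma[:, 1:][int_pin] = -30.0
            max_change = float(np.abs(step).max())
        else:
            R = onehot - P
            # equal slopes: one slope per dimension, alternating conditional
            # Newton updates for the shared slope vector and the intercepts
            u = np.einsum("idk,nd->nidk", np.where(mask[:, :, None], S, 0.0), theta)
            g_a = np.einsum("nik,nidk->d", R, u, optimize=True)
            mu = np.einsum("nik,nidk->nid", P, u, optimize=True)
            aa = np.einsum("nik,nidk,niek->de", P, u, u, optimize=True)
            aa -= np.einsum("nid,nie->de", mu, mu, optimize=True)
            Gamma_a = aa if Gamma_a is None else Gamma_a + gain * (aa - Gamma_a)
            step_a = np.clip(
                gain * np.linalg.solve(Gamma_a + ridge * np.eye(D), g_a),
                -opts.max_step,
                opts.max_step,
            )
            alpha_shared = alpha_shared + step_a

            g_g = R[:, :, 1:].sum(axis=0)
            g_g[int_pin] = 0.0
            Pg = P[:, :, 1:]
            gg = np.zeros((I, P_int, P_int))
            gg[:, np.arange(P_int), np.arange(P_int)] = Pg.sum(axis=0)
            gg -= np.einsum("nik,nim->ikm", Pg, Pg, optimize=True)
            for i, k in zip(*np.nonzero(int_pin)):
                gg[i, k, :] = 0.0
                gg[i, :, k] = 0.0
                gg[i, k, k] = 1.0
            Gamma_g = gg if Gamma_g is None else Gamma_g + gain * (gg - Gamma_g)
            delta_g = np.linalg.solve(
                Gamma_g + ridge * np.eye(P_int), g_g[:, :, None]
            )[:, :, 0]
            step_g = np.clip(gain * delta_g, -opts.max_step, opts.max_step)
            gamma[:, 1:] = gamma[:, 1:] + step_g
            gamma[:, 1:][int_pin] = -30.0
            max_change = float(
                max(np.abs(step_a).max(), np.abs(step_g).max())
            )

        # latent correlation update from imputed second moments
        Semp = theta.T @ theta / N
        Scov = Scov + gain * (Semp - Scov)
        new_corr = _cov2corr(Scov)
        max_change = max(max_change, float(np.abs(new_corr - corr).max()))
        corr = new_corr

        # Polyak-Ruppert averaging over late stage-2 cycles: the averaged
        # trajectory damps the Metropolis wobble of weakly informed
        # parameters, and its settling is the convergence criterion.
        if stage2_t >= opts.min_stage2:
            cur_alpha = alpha_act if constraint_mode == "free" else alpha_shared
            if n_avg == 0:
                avg_alpha = cur_alpha.copy()
                avg_gamma = gamma.copy()
                avg_scov = Scov.copy()
                n_avg = 1
            else:
                n_avg += 1
                d1 = (cur_alpha - avg_alpha) / n_avg
                d2 = (gamma - avg_gamma) / n_avg
                d3 = (Scov - avg_scov) / n_avg
                avg_alpha += d1
                avg_gamma += d2
                avg_scov += d3
                max_change = max(
                    float(np.abs(d1).max()),
                    float(np.abs(d2).max()),
                    float(np.abs(d3).max()),
                )
        trace.append(max_change)
        if n_avg >= max(opts.min_avg, opts.window) and len(trace) >= opts.window:
            if max(trace[-opts.window:]) < opts.tol:
                converged = True
                break

    if not converged and opts.require_convergence:
        raise ConvergenceError(
            f"MH-RM did not converge within {opts.max_cycles} cycles "
            f"(last max change {trace[-1]:.3g})",
            trace=trace,
        )

    # report the averaged stage-2 estimates when averaging has begun
    if n_avg > 0:
        final_alpha, final_gamma = avg_alpha, avg_gamma
        final_corr = _cov2corr(avg_scov)
    else:
        final_alpha = alpha_act if constraint_mode == "free" else alpha_shared
        final_gamma, final_corr = gamma, corr
    final_gamma = final_gamma.copy()
    final_gamma[:, 1:][int_pin] = -30.0
    final_gamma[:, 0] = 0.0

    if constraint_mode == "free":
        alpha_full = np.zeros((I, D))
        np.put_along_axis(alpha_full, active_idx, final_alpha, axis=1)
        n_params = count_free_parameters(I, K1, D, "free", loadings_per_item=L)
    else:
        alpha_full = np.where(mask, final_alpha[None, :], 0.0)
        n_params = count_free_parameters(I, K1, D, "equal")

    params = ItemParameters(slopes=alpha_full, intercepts=final_gamma)
    latent = LatentSpec(roles=weights.dim_roles, corr=final_corr)

    from .model import marginal_loglik

    ll_seed = opts.ll_seed
    if ll_seed is None:
        ll_seed = int(ll_ss.generate_state(1)[0] % (2**31))
    ll = marginal_loglik(
        ResponseMatrix(
            data=responses.data,
            items=responses.items,
            item_traits=responses.item_traits,
            n_categories=responses.n_categories,
        ),
        params,
        weights,
        latent,
        method=opts.ll_method,
        mc_size=opts.ll_mc_size,
        seed=ll_seed,
        n_nodes=opts.ll_nodes,
    )
    return FitResult(
        params=params,
        latent=latent,
        weights=weights,
        loglik=ll,
        ll_method=opts.ll_method,
        n_params=n_params,
        constraint_mode=constraint_mode,
        seed=seed,
        n_persons=N,
        trace=np.asarray(trace),
        n_cycles=n_cycles,
        converged=converged,
        ll_seed=ll_seed if opts.ll_method == "importance" else None,
        ll_mc_size=opts.ll_mc_size if opts.ll_method == "importance" else 0,
    )
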