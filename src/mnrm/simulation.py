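"""Synthetic-data generation and the Monte Carlo recovery/selection study.

The generator emulates a personality questionnaire in which five
substantive traits are each measured by ten items on a 7-point rating
scale, contaminated with extreme and midscale response styles and,
optionally, faking:

1. item slopes drawn U(0.25, 0.75) on every loading dimension; the faking
   column is scaled by K so that faking has trait-equivalent per-category
   impact despite its [0, 1] weight metric, and is fixed at 0 when faking
   is absent;
2. item-specific faking scoring weights in [0, 1] with monotone,
   non-monotone-increasing, or inverted-U desirability trajectories;
3. item-category thresholds tau_ik ~ MVN((-1.5, -0.9, -0.3, 0.3, 0.9,
   1.5), 0.7 I), turned into intercepts gamma_ik = -sum_{m<=k} tau_im
   with gamma_i0 = 0;
4. person parameters MVN(0, Sigma) with unit variances, a fixed trait
   intercorrelation matrix, ERS and MRS orthogonal to everything, and
   faking-trait correlations (.00, .10, -.10, .30, -.30);
5. responses sampled from the multinomial logit.

:func:`run_study` repeats generate-fit-select-measure over replications and
aggregates model-selection proportions and bias/RMSE/Fisher-z recovery
metrics with Monte Carlo standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConvergenceError, ShapeError
from .estimation import (
    FitOptions,
    fit_mnrm,
    map_scores,
    select_model,
)
from .model import (
    ItemParameters,
    LatentSpec,
    ResponseMatrix,
    simulate_responses,
)
from .weights import (
    ERS,
    FAKING,
    MRS,
    ScoringWeightSet,
    assemble_item_weights,
    is_trait_role,
    trait_role,
)

#: Fixed generating intercorrelations of the five substantive traits.
#: The study design calls for moderate positive trait overlap; this matrix
#: keeps all off-diagonals in .10-.30 and is positive definite together
#: with the faking row.
DEFAULT_TRAIT_CORR = np.array(
    [
        [1.00, 0.20, 0.15, 0.15, 0.25],
        [0.20, 1.00, 0.30, 0.20, 0.10],
        [0.15, 0.30, 1.00, 0.20, 0.10],
        [0.15, 0.20, 0.20, 1.00, 0.15],
        [0.25, 0.10, 0.10, 0.15, 1.00],
    ]
)

DEFAULT_FAKING_TRAIT_CORR = (0.00, 0.10, -0.10, 0.30, -0.30)
DEFAULT_THRESHOLD_MEANS = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)

FAKING_SHAPES = ("monotone", "nonmonotone_increasing", "inverted_u")
#: Share of items per trait block assigned to each desirability shape.
FAKING_SHAPE_CENSUS = (0.4, 0.3, 0.3)


@dataclass(frozen=True)
class SimulationDesign:
    """Conditions of one simulated questionnaire study."""

    n_traits: int = 5
    items_per_trait: int = 10
    n_categories: int = 7
    sample_sizes: tuple[int, ...] = (250, 500, 1000, 3000)
    faking_present: bool = True
    replications: int = 50
    threshold_means: tuple[float, ...] = DEFAULT_THRESHOLD_MEANS
    threshold_var: float = 0.7
    slope_bounds: tuple[float, float] = (0.25, 0.75)
    faking_trait_corr: tuple[float, ...] | None = None
    trait_corr: np.ndarray | None = None
    faking_weight_jitter: float = 0.0
    faking_slope_scale: float | None = None
    include_ers: bool = True
    include_mrs: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if min(self.n_traits, self.items_per_trait, self.n_categories) < 1:
            raise ConfigurationError("all design counts must be positive")
        if len(self.threshold_means) != self.n_categories - 1:
            raise ConfigurationError(
                f"need {self.n_categories - 1} threshold means, got "
                f"{len(self.threshold_means)}"
            )
        if self.threshold_var < 0:
            raise ConfigurationError("threshold variance must be >= 0")
        lo, hi = self.slope_bounds
        if not lo < hi:
            raise ConfigurationError("slope bounds must satisfy lo < hi")
        if self.faking_trait_corr is not None and len(self.faking_trait_corr) != self.n_traits:
            raise ConfigurationError(
                "faking_trait_corr must have one entry per trait"
            )

    @property
    def n_items(self) -> int:
        return self.n_traits * self.items_per_trait

    @property
    def dim_roles(self) -> tuple[str, ...]:
        roles = [trait_role(t) for t in range(self.n_traits)]
        if self.include_ers:
            roles.append(ERS)
        if self.include_mrs:
            roles.append(MRS)
        roles.append(FAKING)
        return tuple(roles)

    @property
    def item_traits(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_traits), self.items_per_trait)

    def resolved_trait_corr(self) -> np.ndarray:
        if self.trait_corr is not None:
            return np.asarray(self.trait_corr, dtype=float)
        if self.n_traits > DEFAULT_TRAIT_CORR.shape[0]:
            raise ConfigurationError(
                "no default trait correlations beyond 5 traits; supply trait_corr"
            )
        return DEFAULT_TRAIT_CORR[: self.n_traits, : self.n_traits].copy()

    def resolved_faking_trait_corr(self) -> np.ndarray:
        if self.faking_trait_corr is not None:
            return np.asarray(self.faking_trait_corr, dtype=float)
        if self.n_traits > len(DEFAULT_FAKING_TRAIT_CORR):
            raise ConfigurationError(
                "no default faking-trait correlations beyond 5 traits"
            )
        return np.asarray(DEFAULT_FAKING_TRAIT_CORR[: self.n_traits])


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters behind one simulated dataset."""

    params: ItemParameters
    thresholds: np.ndarray  # I x K
    latent: LatentSpec
    theta: np.ndarray  # N x D
    faking_weights: np.ndarray  # I x (K+1)
    item_traits: np.ndarray


# ---------------------------------------------------------------------------
# Generation steps
# ---------------------------------------------------------------------------

def draw_slopes(
    n_items: int,
    dim_roles: tuple[str, ...],
    item_traits: np.ndarray,
    faking_present: bool,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.25, 0.75),
    faking_slope_scale: float = 1.0,
) -> np.ndarray:
    """Item slopes U(bounds) on loading dimensions, zero elsewhere.

    The faking column is multiplied by ``faking_slope_scale``: faking
    scoring weights live on a [0, 1] metric while trait weights step by 1
    per category, so a scale of K gives the faking dimension
    category-steps of trait-equivalent size ("equivalent impact").  When
    faking is absent the column is identically zero instead, so the
    dimension cannot influence generated responses.
    """
    D = len(dim_roles)
    slopes = np.zeros((n_items, D))
    for d, role in enumerate(dim_roles):
        if is_trait_role(role):
            active = item_traits == int(role[5:]) - 1
            scale = 1.0
        elif role == FAKING:
            if not faking_present:
                continue
            active = np.ones(n_items, dtype=bool)
            scale = faking_slope_scale
        else:
            active = np.ones(n_items, dtype=bool)
            scale = 1.0
        slopes[active, d] = scale * rng.uniform(
            bounds[0], bounds[1], size=active.sum()
        )
    return slopes


def draw_intercepts(
    n_items: int,
    n_categories: int,
    threshold_means: np.ndarray,
    threshold_var: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholds tau ~ MVN(means, var I) and intercepts gamma = -cumsum(tau).

    Returns ``(intercepts (I, K+1), thresholds (I, K))`` with gamma_i0 = 0.
    """
    means = np.asarray(threshold_means, dtype=float)
    K = n_categories - 1
    if means.shape != (K,):
        raise ShapeError(f"need {K} threshold means, got {means.shape}")
    tau = means[None, :] + np.sqrt(threshold_var) * rng.standard_normal((n_items, K))
    gamma = np.zeros((n_items, n_categories))
    gamma[:, 1:] = -np.cumsum(tau, axis=1)
    return gamma, tau


def generate_faking_weights(
    shape: str,
    n_categories: int,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One faking scoring-weight vector in [0, 1] for a desirability shape.

    ``monotone`` is the linear ramp 0..1; ``nonmonotone_increasing`` is the
    ramp with its two middle interior values swapped (an increasing trend
    with one local dip, endpoints 0 and 1); ``inverted_u`` peaks at the
    scale midpoint with endpoints at 0.  Optional uniform jitter of half
    width ``jitter`` is clipped back into [0, 1] (endpoints and the peak
    are left untouched so the shape class is preserved).
    """
    K = n_categories - 1
    if shape == "monotone":
        w = np.linspace(0.0, 1.0, n_categories)
        protected = np.array([0, K])
    elif shape == "nonmonotone_increasing":
        if n_categories < 4:
            raise ConfigurationError(
                "nonmonotone-increasing shape needs at least 4 categories"
            )
        w = np.linspace(0.0, 1.0, n_categories)
        i = n_categories // 2
        w[i - 1], w[i] = w[i], w[i - 1]
        protected = np.array([0, K])
    elif shape == "inverted_u":
        mid = K / 2.0
        w = 1.0 - ((np.arange(n_categories) - mid) / mid) ** 2
        protected = np.array([0, int(round(mid)), K])
    else:
        raise ConfigurationError(f"unknown faking-weight shape {shape!r}")
    if jitter > 0:
        if rng is None:
            raise ConfigurationError("jitter > 0 needs an rng")
        noise = rng.uniform(-jitter, jitter, size=n_categories)
        noise[protected] = 0.0
        w = np.clip(w + noise, 0.0, 1.0)
    return w


def assign_faking_shapes(items_per_trait: int) -> tuple[str, ...]:
    """Deterministic shape census for one trait block.

    Shares of 40% monotone, 30% non-monotone-increasing, and 30%
    inverted-U, apportioned by largest remainder, with monotone items
    first (items 1-4, 5-7, 8-10 in a ten-item block).
    """
    m = items_per_trait
    raw = np.array(FAKING_SHAPE_CENSUS) * m
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for _ in range(m - counts.sum()):
        j = int(np.argmax(rem))
        counts[j] += 1
        rem[j] = -1.0
    return tuple(
        shape for shape, c in zip(FAKING_SHAPES, counts) for _ in range(c)
    )


def build_generating_correlations(design: SimulationDesign) -> np.ndarray:
    """Assemble the generating latent correlation matrix.

    ERS and MRS are orthogonal to each other and to everything else; the
    faking row carries the design's faking-trait correlations.  A
    non-positive-definite assembly is a configuration error.
    """
    roles = design.dim_roles
    D = len(roles)
    C = np.eye(D)
    T = design.resolved_trait_corr()
    nt = design.n_traits
    if T.shape != (nt, nt):
        raise ConfigurationError(f"trait_corr must be {nt}x{nt}")
    C[:nt, :nt] = T
    fk = roles.index(FAKING)
    C[fk, :nt] = C[:nt, fk] = design.resolved_faking_trait_corr()
    if np.linalg.eigvalsh(C).min() <= 1e-10:
        raise ConfigurationError(
            "assembled latent correlation matrix is not positive definite"
        )
    return C


def generate_dataset(
    design: SimulationDesign,
    rng: np.random.Generator | int | None = None,
    n: int | None = None,
) -> tuple[ResponseMatrix, ScoringWeightSet, GroundTruth]:
    """Generate one dataset per the five design steps.

    ``n`` defaults to the design's first sample size.  The generator
    spawns independent substreams for slopes, faking weights, thresholds,
    person parameters, and response sampling, so a model component can be
    varied without perturbing the other draws.
    """
    if rng is None:
        rng = np.random.default_rng(design.master_seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = int(n if n is not None else design.sample_sizes[0])
    r_slopes, r_weights, r_thresh, r_theta, r_resp = rng.spawn(5)

    roles = design.dim_roles
    item_traits = design.item_traits
    I, K1 = design.n_items, design.n_categories

    fss = design.faking_slope_scale
    if fss is None:
        fss = float(K1 - 1)
    slopes = draw_slopes(
        I, roles, item_traits, design.faking_present, r_slopes,
        design.slope_bounds, faking_slope_scale=fss,
    )
    shapes = assign_faking_shapes(design.items_per_trait)
    fw = np.stack(
        [
            generate_faking_weights(
                shapes[i % design.items_per_trait],
                K1,
                design.faking_weight_jitter,
                r_weights,
            )
            for i in range(I)
        ]
    )
    gamma, tau = draw_intercepts(
        I, K1, design.threshold_means, design.threshold_var, r_thresh
    )
    corr = build_generating_correlations(design)
    L = np.linalg.cholesky(corr)
    theta = r_theta.standard_normal((n, len(roles))) @ L.T

    item_map = {f"item{i + 1:03d}": int(item_traits[i]) for i in range(I)}
    fweights = {f"item{i + 1:03d}": fw[i] for i in range(I)}
    wset = assemble_item_weights(
        item_map,
        design.n_traits,
        K1,
        faking_weights=fweights,
        include_ers=design.include_ers,
        include_mrs=design.include_mrs,
    )
    params = ItemParameters(slopes=slopes, intercepts=gamma)
    latent = LatentSpec(roles=roles, corr=corr)
    data = simulate_responses(theta, params, wset, r_resp)
    responses = ResponseMatrix(
        data=data, items=wset.items, item_traits=item_traits, n_categories=K1
    )
    truth = GroundTruth(
        params=params,
        thresholds=tau,
        latent=latent,
        theta=theta,
        faking_weights=fw,
        item_traits=item_traits,
    )
    return responses, wset, truth


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryMetrics:
    bias: float
    rmse: float
    mean_fisher_r: float | None


def fisher_mean_correlation(rs) -> float:
    """Average correlations through Fisher's z: tanh(mean(atanh(r)))."""
    rs = np.asarray(rs, dtype=float)
    rs = np.clip(rs, -1.0 + 1e-12, 1.0 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def recovery_metrics(estimates, truth) -> RecoveryMetrics:
    """Bias, RMSE, and mean Fisher-z correlation of estimates vs truth.

    ``estimates`` and ``truth`` are aligned arrays; with replications on
    the first axis the Fisher-z summary averages the per-replication
    correlation between estimated and true values.  Replications where
    either vector has zero variance are excluded from the correlation with
    a warning (bias and RMSE always use everything).
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.broadcast_to(np.asarray(truth, dtype=float), est.shape)
    if est.shape != tru.shape:
        raise ShapeError("estimates and truth must align")
    err = est - tru
    bias = float(err.mean())
    rmse = float(np.sqrt((err**2).mean()))
    mean_r = None
    if est.ndim >= 2 and est.shape[-1] >= 2:
        flat_e = est.reshape(est.shape[0], -1)
        flat_t = tru.reshape(est.shape[0], -1)
        rs = []
        dropped = 0
        for e, t in zip(flat_e, flat_t):
            if e.std() == 0 or t.std() == 0:
                dropped += 1
                continue
            rs.append(np.corrcoef(e, t)[0, 1])
        if dropped:
            warnings.warn(
                f"{dropped} replications with zero-variance vectors excluded "
                "from the correlation summary",
                stacklevel=2,
            )
        if rs:
            mean_r = fisher_mean_correlation(rs)
    return RecoveryMetrics(bias=bias, rmse=rmse, mean_fisher_r=mean_r)


# ---------------------------------------------------------------------------
# The study runner
# ---------------------------------------------------------------------------

#: The nested model roster of the selection study, as role subsets.
DEFAULT_ROSTER = (
    ("traits", ()),
    ("traits/ERS", (ERS,)),
    ("traits/ERS/MRS", (ERS, MRS)),
    ("traits/ERS/MRS/faking", (ERS, MRS, FAKING)),
)


@dataclass(frozen=True)
class StudyResult:
    """Aggregated selection proportions and recovery metrics of a study."""

    design: SimulationDesign
    roster: tuple[str, ...]
    criteria: tuple[str, ...]
    n_replications: int
    seed: int
    selection: pd.DataFrame = field(repr=False)
    recovery: pd.DataFrame = field(repr=False)
    per_replication: pd.DataFrame = field(repr=False)
    failures: tuple[str, ...] = ()

    def selection_proportions(
        self, sample_size: int, criterion: str
    ) -> pd.Series:
        sel = self.selection
        rows = sel[(sel.sample_size == sample_size) & (sel.criterion == criterion)]
        return rows.set_index("model")["proportion"]


def _trait_pairs(n_traits: int):
    return [(a, b) for a in range(n_traits) for b in range(a + 1, n_traits)]


def _fit_roster(responses, wset, roster, fit_options, rep_ss, ll_seed):
    fits = {}
    for j, (name, styles) in enumerate(roster):
        sub = wset.subset(
            [r for r in wset.dim_roles if is_trait_role(r)] + list(styles)
        )
        fit_seed = int(rep_ss.generate_state(2)[1] % (2**31 - 1)) + j
        opts = replace(fit_options, ll_seed=ll_seed)
        fits[name] = fit_mnrm(responses, sub, "free", opts, seed=fit_seed)
    return fits


def run_study(
    design: SimulationDesign,
    roster=DEFAULT_ROSTER,
    criteria: tuple[str, ...] = ("lr", "aic", "bic"),
    fit_options: FitOptions | None = None,
    seed: int | None = None,
    sample_sizes: tuple[int, ...] | None = None,
    alpha: float = 0.05,
    score_persons: bool = True,
) -> StudyResult:
    """Generate-fit-select-measure over replications and aggregate.

    Per replication and sample size: generate a dataset, fit every roster
    model with free slopes, select a model under each criterion, and
    record recovery metrics (latent-correlation, slope, and MAP
    person-parameter recovery) per fitted model.  Replication-level fit
    failures are recorded and excluded, never silently dropped.  Fully
    reproducible from the master seed.
    """
    fit_options = fit_options or FitOptions()
    seed = design.master_seed if seed is None else int(seed)
    sample_sizes = tuple(sample_sizes or design.sample_sizes)
    names = tuple(name for name, _ in roster)
    R = design.replications

    sel_records = []
    rec_records = []
    rep_records = []
    failures = []
    root = np.random.SeedSequence(seed)
    per_n_ss = root.spawn(len(sample_sizes))

    for n_idx, n in enumerate(sample_sizes):
        rep_sss = per_n_ss[n_idx].spawn(R)
        counts = {c: {m: 0 for m in names} for c in criteria}
        used = 0
        rec_acc: dict[tuple[str, str], list] = {}
        for rep in range(R):
            rep_ss = rep_sss[rep]
            gen_ss, fit_ss, ll_ss = rep_ss.spawn(3)
            responses, wset, truth = generate_dataset(
                design, np.random.default_rng(gen_ss), n=n
            )
            ll_seed = int(ll_ss.generate_state(1)[0] % (2**31))
            try:
                fits = _fit_roster(
                    responses, wset, roster, fit_options, fit_ss, ll_seed
                )
            except ConvergenceError as exc:
                failures.append(f"n={n} rep={rep}: {exc}")
                continue
            used += 1
            fit_list = [fits[m] for m in names]
            for c in criteria:
                chosen = names[select_model(fit_list, c, alpha)]
                counts[c][chosen] += 1
                rep_records.append(
                    {
                        "sample_size": n,
                        "replication": rep,
                        "criterion": c,
                        "selected": chosen,
                    }
                )
            _accumulate_recovery(
                rec_acc, fits, truth, design, score_persons, responses
            )
        for c in criteria:
            for m in names:
                p = counts[c][m] / used if used else np.nan
                sel_records.append(
                    {
                        "sample_size": n,
                        "criterion": c,
                        "model": m,
                        "proportion": p,
                        "mc_se": np.sqrt(p * (1 - p) / used) if used else np.nan,
                        "n_replications": used,
                    }
                )
        for (model, quantity), values in rec_acc.items():
            arr = np.array([v for v in values if v is not None], dtype=float)
            if arr.size == 0:
                continue
            if quantity.startswith("person_"):
                rec_records.append(
                    {
                        "sample_size": n,
                        "model": model,
                        "quantity": quantity,
                        "bias": np.nan,
                        "rmse": np.nan,
                        "fisher_r": fisher_mean_correlation(arr),
                        "mc_se": arr.std(ddof=1) / np.sqrt(arr.size)
                        if arr.size > 1
                        else np.nan,
                        "n_replications": arr.shape[0],
                    }
                )
            else:
                rec_records.append(
                    {
                        "sample_size": n,
                        "model": model,
                        "quantity": quantity,
                        "bias": arr.mean(),
                        "rmse": np.sqrt((arr**2).mean()),
                        "fisher_r": np.nan,
                        "mc_se": arr.mean(axis=1).std(ddof=1) / np.sqrt(arr.shape[0])
                        if arr.ndim > 1 and arr.shape[0] > 1
                        else np.nan,
                        "n_replications": arr.shape[0],
                    }
                )
    return StudyResult(
        design=design,
        roster=names,
        criteria=tuple(criteria),
        n_replications=R,
        seed=seed,
        selection=pd.DataFrame(sel_records),
        recovery=pd.DataFrame(rec_records),
        per_replication=pd.DataFrame(rep_records),
        failures=tuple(failures),
    )


def _accumulate_recovery(acc, fits, truth, design, score_persons, responses):
    """Collect per-replication estimation errors for every fitted model."""
    nt = design.n_traits
    pairs = _trait_pairs(nt)
    true_corr = truth.latent.corr
    true_slopes = truth.params.slopes
    roles = truth.latent.roles
    fk = roles.index(FAKING)
    for model, fit in fits.items():
        C = fit.latent.corr
        errs = [C[a, b] - true_corr[a, b] for a, b in pairs]
        acc.setdefault((model, "trait_trait_corr"), []).append(errs)
        mask_t = fit.weights.loading_mask()
        trait_dims = [
            d for d, r in enumerate(fit.latent.roles) if is_trait_role(r)
        ]
        e_slopes = fit.params.slopes[:, trait_dims][mask_t[:, trait_dims]]
        t_slopes = true_slopes[:, :nt][truth.item_traits[:, None] == np.arange(nt)[None, :]]
        acc.setdefault((model, "trait_slopes"), []).append(e_slopes - t_slopes)
        if FAKING in fit.latent.roles:
            fe = fit.latent.roles.index(FAKING)
            errs = [
                fit.latent.corr[fe, t] - true_corr[fk, t] for t in range(nt)
            ]
            acc.setdefault((model, "faking_trait_corr"), []).append(errs)
            acc.setdefault((model, "faking_slopes"), []).append(
                fit.params.slopes[:, fe] - truth.params.slopes[:, fk]
            )
        if score_persons:
            scores = map_scores(responses, fit)
            rs = []
            for t in range(nt):
                d = fit.latent.roles.index(trait_role(t))
                rs.append(
                    np.corrcoef(scores.scores[:, d], truth.theta[:, t])[0, 1]
                )
            acc.setdefault((model, "person_traits"), []).append(
                fisher_mean_correlation(rs)
            )
            if FAKING in fit.latent.roles:
                fe = fit.latent.roles.index(FAKING)
                acc.setdefault((model, "person_faking"), []).append(
                    np.corrcoef(scores.scores[:, fe], truth.theta[:, fk])[0, 1]
                )
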