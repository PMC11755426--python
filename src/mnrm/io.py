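"""File formats, configuration, and output manifests.

All tabular files are UTF-8 comma-separated with a header row; categories
are 0-based everywhere.  Floats are serialized with 17 significant digits
so write-read round trips are lossless well below 1e-12.

Formats:

* responses: wide CSV, one column per item id, one row per person,
  integer cells in 0..K; the item-to-trait map is a separate CSV with
  columns ``item_id, trait_id``;
* desirability ratings: long CSV ``item_id, category, mean_rating`` with
  the pilot instrument's scale bounds supplied alongside;
* scoring-weight sets: long CSV ``item_id, dimension_role, category,
  weight``;
* fit results: JSON carrying parameters, latent correlations, the
  method-tagged log-likelihood, counts, trace, and the embedded weight
  set (also referenced by content hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MappingError, ShapeError
from .estimation import FitOptions, FitResult, PersonScores
from .model import ItemParameters, LatentSpec, ResponseMatrix
from .simulation import GroundTruth, SimulationDesign, StudyResult
from .weights import DesirabilityRatings, ScoringWeightSet

FLOAT_FMT = "%.17g"
FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Responses and item maps
# ---------------------------------------------------------------------------

def read_item_map(path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"item_id": str})
    if list(df.columns) != ["item_id", "trait_id"]:
        raise ConfigurationError(
            f"item map must have columns item_id, trait_id; got {list(df.columns)}"
        )
    if df.item_id.duplicated().any():
        dup = df.item_id[df.item_id.duplicated()].iloc[0]
        raise MappingError(f"duplicate item id {dup!r} in item map")
    return dict(zip(df.item_id, df.trait_id.astype(int)))


def read_responses(path, item_map: dict[str, int], n_categories: int) -> ResponseMatrix:
    """Read a wide response CSV, validating every cell with row/column context."""
    df = pd.read_csv(path)
    items = list(df.columns)
    if set(items) != set(item_map):
        missing = set(item_map) - set(items)
        extra = set(items) - set(item_map)
        raise MappingError(
            f"response columns disagree with item map (missing {sorted(missing)}, "
            f"unmapped {sorted(extra)})"
        )
    data = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(items):
        vals = df[col].to_numpy()
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (np.mod(numeric.fillna(0), 1) != 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ShapeError(
                f"non-integer response at row {row}, column {col!r}: "
                f"{vals[row]!r}"
            )
        ivals = numeric.astype(np.int64)
        out = (ivals < 0) | (ivals >= n_categories)
        if out.any():
            row = int(np.flatnonzero(out)[0])
            raise ShapeError(
                f"response {ivals.iloc[row]} out of range 0..{n_categories - 1} "
                f"at row {row}, column {col!r}"
            )
        data[:, j] = ivals
    traits = np.array([item_map[i] for i in items], dtype=int)
    return ResponseMatrix(
        data=data, items=tuple(items), item_traits=traits, n_categories=n_categories
    )


def write_responses(responses: ResponseMatrix, path) -> None:
    pd.DataFrame(responses.data, columns=list(responses.items)).to_csv(
        path, index=False
    )


def write_item_map(responses: ResponseMatrix, path) -> None:
    pd.DataFrame(
        {"item_id": list(responses.items), "trait_id": responses.item_traits}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Desirability ratings and weight sets
# ---------------------------------------------------------------------------

def read_desirability(path, lo: float, hi: float) -> DesirabilityRatings:
    df = pd.read_csv(path, dtype={"item_id": str}, float_precision="round_trip")
    need = ["item_id", "category", "mean_rating"]
    if list(df.columns) != need:
        raise ConfigurationError(
            f"desirability CSV must have columns {need}; got {list(df.columns)}"
        )
    items = list(dict.fromkeys(df.item_id))
    K1 = int(df.category.max()) + 1
    ratings = np.full((len(items), K1), np.nan)
    idx = {it: i for i, it in enumerate(items)}
    for _, row in df.iterrows():
        i, k = idx[row.item_id], int(row.category)
        if not np.isnan(ratings[i, k]):
            raise MappingError(
                f"duplicate rating for item {row.item_id!r} category {k}"
            )
        ratings[i, k] = row.mean_rating
    if np.isnan(ratings).any():
        i, k = np.argwhere(np.isnan(ratings))[0]
        raise MappingError(
            f"missing rating for item {items[i]!r} category {k}"
        )
    return DesirabilityRatings(items=tuple(items), ratings=ratings, lo=lo, hi=hi)


def write_weight_set(wset: ScoringWeightSet, path) -> None:
    rows = []
    for i, item in enumerate(wset.items):
        for d, role in enumerate(wset.dim_roles):
            for k in range(wset.n_categories):
                rows.append((item, role, k, wset.weights[i, d, k]))
    pd.DataFrame(
        rows, columns=["item_id", "dimension_role", "category", "weight"]
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_weight_set(path) -> ScoringWeightSet:
    df = pd.read_csv(
        path,
        dtype={"item_id": str, "dimension_role": str},
        float_precision="round_trip",
    )
    items = list(dict.fromkeys(df.item_id))
    roles = list(dict.fromkeys(df.dimension_role))
    K1 = int(df.category.max()) + 1
    W = np.zeros((len(items), len(roles), K1))
    ii = {v: i for i, v in enumerate(items)}
    dd = {v: d for d, v in enumerate(roles)}
    for t in df.itertuples(index=False):
        W[ii[t.item_id], dd[t.dimension_role], int(t.category)] = t.weight
    # recover each item's trait from the nonzero own-trait row
    trait_dims = [d for d, r in enumerate(roles) if r.startswith("trait")]
    traits = np.zeros(len(items), dtype=int)
    for i in range(len(items)):
        nz = [d for d in trait_dims if np.any(W[i, d] != 0)]
        if len(nz) != 1:
            raise MappingError(
                f"item {items[i]!r} must have exactly one nonzero trait row"
            )
        traits[i] = int(roles[nz[0]][5:]) - 1
    return ScoringWeightSet(
        items=tuple(items), dim_roles=tuple(roles), weights=W, item_traits=traits
    )


# ---------------------------------------------------------------------------
# Fit results and scores
# ---------------------------------------------------------------------------

def fit_to_dict(fit: FitResult) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "slopes": fit.params.slopes.tolist(),
        "intercepts": fit.params.intercepts.tolist(),
        "corr": fit.latent.corr.tolist(),
        "roles": list(fit.latent.roles),
        "weights": {
            "items": list(fit.weights.items),
            "dim_roles": list(fit.weights.dim_roles),
            "item_traits": fit.weights.item_traits.tolist(),
            "weights": fit.weights.weights.tolist(),
        },
        "weights_hash": fit.weights.content_hash(),
        "loglik": fit.loglik,
        "ll_method": fit.ll_method,
        "ll_seed": fit.ll_seed,
        "ll_mc_size": fit.ll_mc_size,
        "n_params": fit.n_params,
        "constraint_mode": fit.constraint_mode,
        "seed": fit.seed,
        "n_persons": fit.n_persons,
        "trace": fit.trace.tolist(),
        "n_cycles": fit.n_cycles,
        "converged": fit.converged,
    }


def fit_from_dict(d: dict) -> FitResult:
    w = d["weights"]
    wset = ScoringWeightSet(
        items=tuple(w["items"]),
        dim_roles=tuple(w["dim_roles"]),
        weights=np.asarray(w["weights"]),
        item_traits=np.asarray(w["item_traits"]),
    )
    if d.get("weights_hash") and wset.content_hash() != d["weights_hash"]:
        raise MappingError("weight set does not match its recorded content hash")
    return FitResult(
        params=ItemParameters(
            slopes=np.asarray(d["slopes"]), intercepts=np.asarray(d["intercepts"])
        ),
        latent=LatentSpec(roles=tuple(d["roles"]), corr=np.asarray(d["corr"])),
        weights=wset,
        loglik=float(d["loglik"]),
        ll_method=d["ll_method"],
        n_params=int(d["n_params"]),
        constraint_mode=d["constraint_mode"],
        seed=int(d["seed"]),
        n_persons=int(d["n_persons"]),
        trace=np.asarray(d["trace"]),
        n_cycles=int(d["n_cycles"]),
        converged=bool(d["converged"]),
        ll_seed=d.get("ll_seed"),
        ll_mc_size=int(d.get("ll_mc_size") or 0),
    )


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=1))


def read_fit(path) -> FitResult:
    return fit_from_dict(json.loads(Path(path).read_text()))


def write_scores(scores: PersonScores, path) -> None:
    df = pd.DataFrame(scores.scores, columns=list(scores.roles))
    df["converged"] = scores.converged
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_PATH_KEYS = {"responses", "item_map", "desirability", "weights", "out"}


@dataclass(frozen=True)
class ConfigProfile:
    """Validated configuration: paths, model roster, estimation, design."""

    paths: dict = field(default_factory=dict)
    n_categories: int | None = None
    scale_bounds: tuple[float, float] | None = None
    estimation: FitOptions = field(default_factory=FitOptions)
    design: SimulationDesign | None = None
    roster: tuple[str, ...] | None = None
    seed: int = 0


def load_config(path) -> ConfigProfile:
    """Strictly parse a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    allowed = {
        "version",
        "paths",
        "n_categories",
        "scale_bounds",
        "estimation",
        "design",
        "roster",
        "seed",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if raw.get("version", FORMAT_VERSION) != FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported config version {raw.get('version')!r}"
        )
    paths = raw.get("paths") or {}
    if not isinstance(paths, dict) or set(paths) - _PATH_KEYS:
        raise ConfigurationError(
            f"paths section may only contain {sorted(_PATH_KEYS)}"
        )
    for key, p in paths.items():
        if key != "out" and not Path(p).exists():
            raise ConfigurationError(f"configured {key} file does not exist: {p}")
    est_raw = raw.get("estimation") or {}
    opt_fields = {f.name for f in fields(FitOptions)}
    unknown = set(est_raw) - opt_fields
    if unknown:
        raise ConfigurationError(f"unknown estimation options: {sorted(unknown)}")
    if "accept_target" in est_raw:
        est_raw["accept_target"] = tuple(est_raw["accept_target"])
    estimation = FitOptions(**est_raw)
    design = None
    if raw.get("design") is not None:
        d_raw = dict(raw["design"])
        design_fields = {f.name for f in fields(SimulationDesign)}
        unknown = set(d_raw) - design_fields
        if unknown:
            raise ConfigurationError(f"unknown design keys: {sorted(unknown)}")
        for key in ("sample_sizes", "threshold_means", "slope_bounds", "faking_trait_corr"):
            if key in d_raw and d_raw[key] is not None:
                d_raw[key] = tuple(d_raw[key])
        if d_raw.get("trait_corr") is not None:
            d_raw["trait_corr"] = np.asarray(d_raw["trait_corr"], dtype=float)
        design = SimulationDesign(**d_raw)
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigurationError(f"seed must be an integer, got {seed!r}")
    bounds = raw.get("scale_bounds")
    return ConfigProfile(
        paths=paths,
        n_categories=raw.get("n_categories"),
        scale_bounds=tuple(bounds) if bounds else None,
        estimation=estimation,
        design=design,
        roster=tuple(raw["roster"]) if raw.get("roster") else None,
        seed=seed,
    )


def load_inputs(config: ConfigProfile):
    """Resolve a config into typed inputs.

    Returns ``(primary, secondary)`` where primary is a
    :class:`SimulationDesign` (simulation configs) or
    :class:`ResponseMatrix` (data configs) and secondary is a weight set,
    desirability ratings, or None.
    """
    primary = None
    if config.design is not None:
        primary = config.design
    elif "responses" in config.paths:
        if "item_map" not in config.paths or config.n_categories is None:
            raise ConfigurationError(
                "responses need an item_map path and n_categories"
            )
        item_map = read_item_map(config.paths["item_map"])
        primary = read_responses(
            config.paths["responses"], item_map, config.n_categories
        )
    else:
        raise ConfigurationError("config supplies neither a design nor responses")
    secondary = None
    if "weights" in config.paths:
        secondary = read_weight_set(config.paths["weights"])
    elif "desirability" in config.paths:
        if config.scale_bounds is None:
            raise ConfigurationError("desirability ratings need scale_bounds")
        lo, hi = config.scale_bounds
        secondary = read_desirability(config.paths["desirability"], lo, hi)
    return primary, secondary


# ---------------------------------------------------------------------------
# Output manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(results: dict, out_dir, seed: int | None = None,
                  config_hash: str | None = None) -> dict:
    """Write result objects under ``out_dir`` and a manifest listing them.

    Layout is deterministic (one file per result, sorted manifest); the
    manifest records a SHA-256 per artifact plus run metadata.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []

    def record(path: Path):
        artifacts.append({"name": path.name, "sha256": _sha256(path)})

    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, FitResult):
            p = out / f"{name}.json"
            write_fit(obj, p)
            record(p)
        elif isinstance(obj, StudyResult):
            p = out / f"{name}_selection.csv"
            obj.selection.to_csv(p, index=False, float_format=FLOAT_FMT)
            record(p)
            p = out / f"{name}_recovery.csv"
            obj.recovery.to_csv(p, index=False, float_format=FLOAT_FMT)
            record(p)
            p = out / f"{name}_replications.jsonl"
            with open(p, "w") as fh:
                for rec in obj.per_replication.to_dict("records"):
                    fh.write(json.dumps(rec) + "\n")
            record(p)
        elif isinstance(obj, ResponseMatrix):
            p = out / f"{name}.csv"
            write_responses(obj, p)
            record(p)
            p = out / f"{name}_item_map.csv"
            write_item_map(obj, p)
            record(p)
        elif isinstance(obj, ScoringWeightSet):
            p = out / f"{name}.csv"
            write_weight_set(obj, p)
            record(p)
        elif isinstance(obj, PersonScores):
            p = out / f"{name}.csv"
            write_scores(obj, p)
            record(p)
        elif isinstance(obj, GroundTruth):
            p = out / f"{name}.json"
            p.write_text(
                json.dumps(
                    {
                        "slopes": obj.params.slopes.tolist(),
                        "intercepts": obj.params.intercepts.tolist(),
                        "thresholds": obj.thresholds.tolist(),
                        "corr": obj.latent.corr.tolist(),
                        "roles": list(obj.latent.roles),
                        "theta": obj.theta.tolist(),
                        "faking_weights": obj.faking_weights.tolist(),
                        "item_traits": obj.item_traits.tolist(),
                    },
                    indent=1,
                )
            )
            record(p)
        elif isinstance(obj, dict):
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, sort_keys=True))
            record(p)
        else:
            raise ConfigurationError(
                f"no writer for result {name!r} of type {type(obj).__name__}"
            )

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
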