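"""Scoring-weight construction for traits, response styles, and faking.

In the multidimensional nominal response model each latent dimension d is
linked to category k of item i through a fixed scoring weight ``s_idk``.
Substantive traits use equally spaced weights (0, 1, ..., K), extreme
response style (ERS) weights the two endpoint categories, midscale response
style (MRS) weights the scale midpoint, and a faking dimension uses
item-specific weights derived from social-desirability ratings of each
response category, rescaled to the unit interval.

Dimension ordering is fixed everywhere as traits, then ERS, then MRS, then
faking.
"""

from __future__ import annotations

import hashlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateWeightsError,
    InvalidCategoriesError,
    MappingError,
    NoMidpointError,
    ShapeError,
    WeightRangeError,
    ZeroRangeError,
)

ERS = "ers"
MRS = "mrs"
FAKING = "faking"
STYLE_ROLES = (ERS, MRS, FAKING)


def trait_role(index: int) -> str:
    """Role tag of the substantive trait with 0-based ``index``."""
    return f"trait{index + 1}"


def is_trait_role(role: str) -> bool:
    return role.startswith("trait")


def trait_index(role: str) -> int:
    """0-based trait index encoded in a trait role tag."""
    if not is_trait_role(role):
        raise MappingError(f"not a trait role: {role!r}")
    return int(role[5:]) - 1


def trait_weight_vector(n_categories: int) -> np.ndarray:
    """Equally spaced weights (0, 1, ..., K) for a substantive trait.

    Higher trait levels then raise the odds of higher categories.
    """
    if n_categories < 2:
        raise InvalidCategoriesError(
            f"a trait weight vector needs at least 2 categories, got {n_categories}"
        )
    return np.arange(n_categories, dtype=float)


def ers_weight_vector(n_categories: int) -> np.ndarray:
    """Endpoint-indicator weights (1, 0, ..., 0, 1) for extreme response style.

    With only two categories the vector would be constant and cancel from
    the multinomial logit, so that case is rejected.
    """
    if n_categories < 3:
        raise DegenerateWeightsError(
            "ERS weights are constant (and cancel from the model) for "
            f"{n_categories} categories; need at least 3"
        )
    w = np.zeros(n_categories)
    w[0] = w[-1] = 1.0
    return w


def mrs_weight_vector(n_categories: int) -> np.ndarray:
    """Midpoint-indicator weights (0, ..., 1, ..., 0) for midscale response style."""
    if n_categories < 3 or n_categories % 2 == 0:
        raise NoMidpointError(
            f"a scale with {n_categories} categories has no single midpoint"
        )
    w = np.zeros(n_categories)
    w[n_categories // 2] = 1.0
    return w


@dataclass(frozen=True)
class DesirabilityRatings:
    """Mean desirability rating of every response category of every item.

    ``ratings`` holds one mean rating per (item, category) pair on the pilot
    instrument's own scale with global bounds ``(lo, hi)``.
    """

    items: tuple[str, ...]
    ratings: np.ndarray  # I x (K+1)
    lo: float
    hi: float

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        ratings = np.asarray(self.ratings, dtype=float)
        object.__setattr__(self, "ratings", ratings)
        if ratings.ndim != 2 or ratings.shape[0] != len(self.items):
            raise ShapeError(
                f"ratings must be (n_items, n_categories), got {ratings.shape}"
            )
        if not self.lo < self.hi:
            raise ZeroRangeError(
                f"rating-scale bounds must satisfy lo < hi, got [{self.lo}, {self.hi}]"
            )
        if not np.all(np.isfinite(ratings)):
            raise ShapeError("ratings contain non-finite values")
        if ratings.min() < self.lo or ratings.max() > self.hi:
            raise WeightRangeError(
                "ratings fall outside the declared scale bounds "
                f"[{self.lo}, {self.hi}]"
            )

    @property
    def n_categories(self) -> int:
        return self.ratings.shape[1]


def rescale_desirability(
    ratings: DesirabilityRatings, *, per_item: bool = False
) -> dict[str, np.ndarray]:
    """Affinely map desirability ratings onto [0, 1] faking scoring weights.

    By default the instrument's *global* scale bounds are used, ``w = (r -
    lo) / (hi - lo)``, so that between-item differences in desirability
    level are preserved and the faking weights share one metric across
    items.  ``per_item=True`` instead stretches each item to its own
    min/max; this equalizes items whose trajectories differ only in level
    and is offered for sensitivity analyses, not as the default.
    """
    out: dict[str, np.ndarray] = {}
    for i, item in enumerate(ratings.items):
        r = ratings.ratings[i]
        if per_item:
            lo, hi = float(r.min()), float(r.max())
            if hi == lo:
                raise ZeroRangeError(
                    f"item {item!r} has constant ratings; per-item rescaling "
                    "is undefined"
                )
        else:
            lo, hi = ratings.lo, ratings.hi
        out[item] = (r - lo) / (hi - lo)
    return out


@dataclass(frozen=True)
class ScoringWeightSet:
    """Per-item D x (K+1) scoring-weight matrices with dimension roles.

    Row order is traits, then ERS, then MRS, then faking (any of the style
    rows may be absent).  For an item assigned to trait t, every other
    trait row is zero and the own-trait row is (0, 1, ..., K).
    """

    items: tuple[str, ...]
    dim_roles: tuple[str, ...]
    weights: np.ndarray  # I x D x (K+1)
    item_traits: np.ndarray = field(repr=False)  # I, 0-based trait index

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "dim_roles", tuple(self.dim_roles))
        object.__setattr__(
            self, "weights", np.asarray(self.weights, dtype=float)
        )
        object.__setattr__(
            self, "item_traits", np.asarray(self.item_traits, dtype=int)
        )
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_dim(self) -> int:
        return len(self.dim_roles)

    @property
    def n_categories(self) -> int:
        return self.weights.shape[2]

    @property
    def n_traits(self) -> int:
        return sum(1 for r in self.dim_roles if is_trait_role(r))

    def role_index(self, role: str) -> int:
        try:
            return self.dim_roles.index(role)
        except ValueError:
            raise MappingError(f"role {role!r} not in {self.dim_roles}") from None

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        I, D, K1 = self.weights.shape
        if I != len(self.items) or D != len(self.dim_roles):
            raise ShapeError(
                f"weights shape {self.weights.shape} inconsistent with "
                f"{len(self.items)} items and roles {self.dim_roles}"
            )
        if len(set(self.items)) != I:
            raise MappingError("duplicate item identifiers")
        if self.item_traits.shape != (I,):
            raise ShapeError("item_traits must have one entry per item")
        trait_dims = [d for d, r in enumerate(self.dim_roles) if is_trait_role(r)]
        trait_of_dim = {d: trait_index(self.dim_roles[d]) for d in trait_dims}
        tvec = trait_weight_vector(K1)
        for i in range(I):
            t = self.item_traits[i]
            for d in trait_dims:
                row = self.weights[i, d]
                if trait_of_dim[d] == t:
                    if not np.array_equal(row, tvec):
                        raise MappingError(
                            f"item {self.items[i]!r}: own-trait row must be "
                            f"(0..{K1 - 1})"
                        )
                elif np.any(row != 0):
                    raise MappingError(
                        f"item {self.items[i]!r}: off-trait row "
                        f"{self.dim_roles[d]!r} must be all zeros"
                    )
        for role, maker in ((ERS, ers_weight_vector), (MRS, mrs_weight_vector)):
            if role in self.dim_roles:
                expected = maker(K1)
                rows = self.weights[:, self.role_index(role), :]
                if not np.all(rows == expected):
                    raise MappingError(f"{role.upper()} rows must equal {expected}")
        if FAKING in self.dim_roles:
            rows = self.weights[:, self.role_index(FAKING), :]
            if rows.min() < 0 or rows.max() > 1:
                raise WeightRangeError("faking weights must lie in [0, 1]")

    # -- derived structures ---------------------------------------------
    def loading_mask(self) -> np.ndarray:
        """Boolean (I, D) mask of dimensions each item loads on.

        An item loads on its own trait and on every style/faking dimension.
        """
        mask = np.zeros((self.n_items, self.n_dim), dtype=bool)
        for d, role in enumerate(self.dim_roles):
            if is_trait_role(role):
                mask[:, d] = self.item_traits == trait_index(role)
            else:
                mask[:, d] = True
        return mask

    def subset(self, roles: Sequence[str]) -> "ScoringWeightSet":
        """Weight set restricted to ``roles`` (order preserved from self)."""
        keep = [d for d, r in enumerate(self.dim_roles) if r in set(roles)]
        if not any(is_trait_role(self.dim_roles[d]) for d in keep):
            raise MappingError("a weight set must keep at least one trait")
        return ScoringWeightSet(
            items=self.items,
            dim_roles=tuple(self.dim_roles[d] for d in keep),
            weights=self.weights[:, keep, :],
            item_traits=self.item_traits,
        )

    def content_hash(self) -> str:
        """SHA-256 over a canonical serialization; ties fits to weight sets."""
        h = hashlib.sha256()
        h.update("|".join(self.items).encode())
        h.update("|".join(self.dim_roles).encode())
        h.update(self.item_traits.tobytes())
        h.update(np.ascontiguousarray(self.weights).tobytes())
        return h.hexdigest()


def assemble_item_weights(
    item_trait_map: Mapping[str, int],
    n_traits: int,
    n_categories: int,
    faking_weights: Mapping[str, np.ndarray] | None = None,
    include_ers: bool = True,
    include_mrs: bool = True,
) -> ScoringWeightSet:
    """Build the full scoring-weight set from an item-to-trait map.

    ``item_trait_map`` maps item id to 0-based trait index and fixes the
    item order.  ``faking_weights`` (item id -> length-(K+1) vector in
    [0, 1]) must be given exactly when a faking dimension is wanted.
    """
    items = tuple(item_trait_map)
    traits = np.array([item_trait_map[i] for i in items], dtype=int)
    if traits.size and (traits.min() < 0 or traits.max() >= n_traits):
        bad = items[int(np.argmax((traits < 0) | (traits >= n_traits)))]
        raise MappingError(
            f"item {bad!r} mapped to unknown trait (have {n_traits} traits)"
        )
    roles = [trait_role(t) for t in range(n_traits)]
    if include_ers:
        roles.append(ERS)
    if include_mrs:
        roles.append(MRS)
    if faking_weights is not None:
        roles.append(FAKING)

    K1 = n_categories
    W = np.zeros((len(items), len(roles), K1))
    tvec = trait_weight_vector(K1)
    for i, item in enumerate(items):
        W[i, traits[i]] = tvec
        d = n_traits
        if include_ers:
            W[i, d] = ers_weight_vector(K1)
            d += 1
        if include_mrs:
            W[i, d] = mrs_weight_vector(K1)
            d += 1
        if faking_weights is not None:
            if item not in faking_weights:
                raise MappingError(f"no faking weights for item {item!r}")
            fw = np.asarray(faking_weights[item], dtype=float)
            if fw.shape != (K1,):
                raise ShapeError(
                    f"faking weights for item {item!r} must have length {K1}"
                )
            if fw.min() < 0 or fw.max() > 1:
                raise WeightRangeError(
                    f"faking weights for item {item!r} outside [0, 1]"
                )
            W[i, d] = fw
    return ScoringWeightSet(
        items=items, dim_roles=tuple(roles), weights=W, item_traits=traits
    )
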