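"""Core data model and likelihood kernels of the multidimensional nominal
response model (MNRM).

The MNRM is a divide-by-total IRT model for categorical item responses driven
by several latent dimensions at once.  The probability that person ``n`` picks
category ``k`` (of K+1) on item ``i`` is a multinomial logistic function

    p(Y_ni = k | theta_n) = softmax_k( sum_d alpha_id * s_idk * theta_nd + gamma_ik )

with item slopes ``alpha_id``, fixed scoring weights ``s_idk``, and category
intercepts ``gamma_ik``.  Identification fixes the first intercept of every
item to 0 and the latent distribution to multivariate normal with mean 0 and
unit variances (so latent scores are on a z-score metric).

Latent dimensions play three roles: substantive traits (one per item), an
extreme-response-style dimension, and a faking dimension whose scoring weights
encode the desirability trajectory of each item's categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MISSING",
    "Dimension",
    "ModelSpec",
    "ItemParameters",
    "LatentDistribution",
    "PersonParameters",
    "ResponseMatrix",
    "ModelStructureError",
    "category_probabilities",
    "log_likelihood",
    "apply_identification",
    "IdentificationResult",
]

#: Sentinel for a missing response cell.  The simulator never produces missing
#: values; the likelihood skips cells equal to this sentinel if present.
MISSING = -1

_ROLES = ("trait", "ers", "faking")


class ModelStructureError(ValueError):
    """Raised when shapes or dimension structures do not agree."""


@dataclass(frozen=True)
class Dimension:
    """One latent dimension: a label plus its role (trait / ers / faking)."""

    label: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")


@dataclass
class ModelSpec:
    """Structure of an MNRM: rating-scale length, dimensions, item loadings.

    Every item loads on exactly one trait dimension (given by ``item_trait``);
    ERS and faking dimensions, when present, load on all items.
    """

    n_categories: int
    dimensions: List[Dimension]
    item_ids: List[str]
    item_trait: Dict[str, str]

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("n_categories (K+1) must be at least 2")
        labels = [d.label for d in self.dimensions]
        if len(set(labels)) != len(labels):
            raise ValueError("dimension labels must be unique")
        trait_labels = {d.label for d in self.dimensions if d.role == "trait"}
        if not trait_labels:
            raise ValueError("at least one trait dimension is required")
        for role in ("ers", "faking"):
            if sum(d.role == role for d in self.dimensions) > 1:
                raise ValueError(f"at most one {role} dimension is allowed")
        missing = [i for i in self.item_ids if i not in self.item_trait]
        if missing:
            raise ValueError(f"items without a trait assignment: {missing}")
        bad = {i: t for i, t in self.item_trait.items() if t not in trait_labels}
        if bad:
            raise ValueError(f"items mapped to unknown trait dimensions: {bad}")

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def trait_indices(self) -> List[int]:
        return [j for j, d in enumerate(self.dimensions) if d.role == "trait"]

    @property
    def bias_indices(self) -> List[int]:
        return [j for j, d in enumerate(self.dimensions) if d.role != "trait"]

    @property
    def ers_index(self) -> Optional[int]:
        for j, d in enumerate(self.dimensions):
            if d.role == "ers":
                return j
        return None

    @property
    def faking_index(self) -> Optional[int]:
        for j, d in enumerate(self.dimensions):
            if d.role == "faking":
                return j
        return None

    def dimension_index(self, label: str) -> int:
        for j, d in enumerate(self.dimensions):
            if d.label == label:
                return j
        raise KeyError(label)

    def loaded_dimensions(self, item_id: str) -> List[int]:
        """Indices of the dimensions item ``item_id`` loads on (trait first)."""
        return [self.dimension_index(self.item_trait[item_id])] + self.bias_indices


@dataclass
class ItemParameters:
    """Slopes, intercepts, and scoring weights of one item.

    ``slopes`` has length D, ``intercepts`` length K+1 (first entry 0 under the
    identification constraints), and ``scoring_weights`` is D x (K+1) on the
    common 0..6 metric.  Rows of ``scoring_weights`` for dimensions the item
    does not load on are all-zero (or carry slope 0).
    """

    slopes: np.ndarray
    intercepts: np.ndarray
    scoring_weights: np.ndarray
    item_id: str = ""

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.scoring_weights = np.asarray(self.scoring_weights, dtype=float)
        if self.slopes.ndim != 1 or self.intercepts.ndim != 1:
            raise ModelStructureError("slopes and intercepts must be vectors")
        if self.scoring_weights.shape != (self.slopes.size, self.intercepts.size):
            raise ModelStructureError(
                "scoring_weights must be D x (K+1) = "
                f"{(self.slopes.size, self.intercepts.size)}, "
                f"got {self.scoring_weights.shape}"
            )
        for arr in (self.slopes, self.intercepts, self.scoring_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("item parameters must be finite")

    @property
    def n_dimensions(self) -> int:
        return self.slopes.size

    @property
    def n_categories(self) -> int:
        return self.intercepts.size

    @property
    def loading_matrix(self) -> np.ndarray:
        """D x (K+1) matrix of ``alpha_id * s_idk`` (predictor coefficients)."""
        return self.slopes[:, None] * self.scoring_weights

    def is_identified(self, atol: float = 1e-10) -> bool:
        return abs(float(self.intercepts[0])) <= atol


@dataclass
class LatentDistribution:
    """Multivariate-normal latent distribution: mean vector and covariance.

    Under the identification constraints the mean is 0 and the covariance is a
    correlation matrix (unit diagonal, symmetric, positive definite).
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.mean.size
        if self.covariance.shape != (d, d):
            raise ModelStructureError("covariance must be D x D")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def n_dimensions(self) -> int:
        return self.mean.size

    def is_identified(self, atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.mean, 0.0, atol=atol)
            and np.allclose(np.diag(self.covariance), 1.0, atol=atol)
        )

    def assert_positive_definite(self) -> None:
        eigmin = float(np.linalg.eigvalsh(self.covariance).min())
        if eigmin <= 1e-10:
            raise ValueError(f"covariance is not positive definite (eigmin={eigmin:g})")


@dataclass
class PersonParameters:
    """N x D matrix of latent scores on the z-score metric."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("person parameters must be finite")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseMatrix:
    """N x I integer responses with categories 0..K (MISSING marks absent cells)."""

    values: np.ndarray
    item_ids: List[str] = field(default_factory=list)
    person_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.int64))
        n, i = self.values.shape
        if not self.item_ids:
            self.item_ids = [f"item{j + 1:03d}" for j in range(i)]
        if not self.person_ids:
            self.person_ids = [f"p{j + 1:05d}" for j in range(n)]
        if len(self.item_ids) != i:
            raise ModelStructureError("item_ids length must match column count")
        if len(self.person_ids) != n:
            raise ModelStructureError("person_ids length must match row count")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def validate_categories(self, n_categories: int) -> None:
        vals = self.values
        observed = vals != MISSING
        if observed.any():
            lo = vals[observed].min()
            hi = vals[observed].max()
            if lo < 0 or hi >= n_categories:
                raise ValueError(
                    f"responses outside 0..{n_categories - 1} found "
                    f"(min={lo}, max={hi})"
                )


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------


def category_probabilities(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Category probabilities for one item at latent position ``theta``.

    Computed with a log-sum-exp stabilized softmax over
    ``sum_d alpha_id s_idk theta_d + gamma_ik``; the result is a length-(K+1)
    probability vector summing to 1.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (item.n_dimensions,):
        raise ModelStructureError(
            f"theta must have shape ({item.n_dimensions},), got {theta.shape}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    pred = theta @ item.loading_matrix + item.intercepts
    pred -= pred.max()
    p = np.exp(pred)
    return p / p.sum()


def stack_loading_matrices(items: Sequence[ItemParameters]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack items into (B, gamma): B is D x (I*(K+1)), gamma is I x (K+1).

    ``theta @ B`` reshaped to (N, I, K+1) plus gamma gives all predictors in a
    single BLAS call; used by the simulator, the samplers, and scoring.
    """
    a = np.stack([it.loading_matrix for it in items])  # (I, D, K+1)
    gamma = np.stack([it.intercepts for it in items])  # (I, K+1)
    i, d, k1 = a.shape
    b = a.transpose(1, 0, 2).reshape(d, i * k1)
    return b, gamma


def all_log_probabilities(
    theta: np.ndarray, b: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    """(N, I, K+1) log category probabilities for stacked items."""
    n = theta.shape[0]
    i, k1 = gamma.shape
    pred = (theta @ b).reshape(n, i, k1) + gamma
    return pred - logsumexp(pred, axis=-1, keepdims=True)


def person_log_likelihood(
    theta: np.ndarray,
    responses: np.ndarray,
    b: np.ndarray,
    gamma: np.ndarray,
) -> np.ndarray:
    """Per-person log-likelihood sum over items; missing cells are skipped."""
    lp = all_log_probabilities(theta, b, gamma)
    observed = responses != MISSING
    safe = np.where(observed, responses, 0)
    cell = np.take_along_axis(lp, safe[:, :, None], axis=2)[:, :, 0]
    return np.where(observed, cell, 0.0).sum(axis=1)


def log_likelihood(
    responses: ResponseMatrix,
    persons: PersonParameters,
    items: Sequence[ItemParameters],
) -> float:
    """Joint log-likelihood of all responses given person and item parameters."""
    if persons.n_persons != responses.n_persons:
        raise ModelStructureError("persons and responses disagree on N")
    if len(items) != responses.n_items:
        raise ModelStructureError("item list and responses disagree on I")
    k1 = items[0].n_categories
    responses.validate_categories(k1)
    b, gamma = stack_loading_matrices(items)
    return float(person_log_likelihood(persons.values, responses.values, b, gamma).sum())


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------


@dataclass
class IdentificationResult:
    """Constrained parameters plus a record of the transforms applied."""

    items: List[ItemParameters]
    latent: LatentDistribution
    applied: List[str]
    scale: np.ndarray
    mean_shift: np.ndarray


def apply_identification(
    spec: ModelSpec,
    items: Sequence[ItemParameters],
    latent: LatentDistribution,
) -> IdentificationResult:
    """Map parameters onto the identified scale, preserving the likelihood.

    Three likelihood-preserving transforms are applied as needed: the latent
    mean is absorbed into the intercepts and set to 0; latent variances are
    rescaled to 1 with slopes compensated by the standard deviations; and each
    item's intercepts are shifted so that the first-category intercept is 0
    (softmax shift invariance).  Already-constrained input is returned
    unchanged (up to exact arithmetic), making the operation idempotent.
    """
    applied: List[str] = []
    mean = latent.mean.copy()
    cov = latent.covariance.copy()
    new_items = [replace(it) for it in items]

    mean_shift = np.zeros_like(mean)
    if not np.allclose(mean, 0.0, atol=1e-12):
        mean_shift = mean.copy()
        for it in new_items:
            it.intercepts = it.intercepts + mean_shift @ it.loading_matrix
        mean = np.zeros_like(mean)
        applied.append("latent_mean_zeroed")

    sd = np.sqrt(np.diag(cov))
    scale = sd.copy()
    if not np.allclose(sd, 1.0, atol=1e-12):
        for it in new_items:
            it.slopes = it.slopes * sd
        cov = cov / np.outer(sd, sd)
        applied.append("latent_variances_unit")
    np.fill_diagonal(cov, 1.0)

    shifted = False
    for it in new_items:
        g0 = float(it.intercepts[0])
        if g0 != 0.0:
            it.intercepts = it.intercepts - g0
            shifted = True
    if shifted:
        applied.append("first_intercept_zeroed")

    return IdentificationResult(
        items=new_items,
        latent=LatentDistribution(mean=mean, covariance=cov),
        applied=applied,
        scale=scale,
        mean_shift=mean_shift,
    )
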