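"""Synthetic questionnaire data with substantive traits, ERS, and faking.

The generator reproduces the factorial simulation design of the study the
package implements: five substantive traits measured on a seven-point Likert
scale, crossed over five compositions of item desirability trajectories,
test length (6 vs 12 items per trait), sample size (500/1000/2000), presence
of extreme response style, and faking impact (none/low/high) — 180 conditions.

Data generation per replication proceeds in six steps: draw item slopes, fix
scoring weights, draw category thresholds and convert them to intercepts, draw
person parameters from a multivariate normal with the meta-analytic Big Five
intercorrelations (randomly assigned to trait pairs), simulate categorical
responses from the MNRM, and record the generating truth in a manifest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Dimension,
    ItemParameters,
    LatentDistribution,
    ModelSpec,
    PersonParameters,
    ResponseMatrix,
    all_log_probabilities,
    stack_loading_matrices,
)
from .weights import FAKING_PROTOTYPES, TRAJECTORY_ORDER, prototype_weights

__all__ = [
    "SimulationCondition",
    "TruthManifest",
    "COMPOSITION_PROPORTIONS",
    "TRAIT_PAIR_CORRELATIONS",
    "FAKING_TRAIT_CORRELATIONS",
    "enumerate_design",
    "build_composition",
    "make_model_spec",
    "draw_item_parameters",
    "draw_trait_pair_sigma",
    "draw_persons",
    "sample_responses",
    "simulate_dataset",
]

N_TRAITS = 5
DEFAULT_REPLICATIONS = 100

#: Trajectory mixture per composition (fractions per trait scale).
COMPOSITION_PROPORTIONS: Dict[int, Dict[str, float]] = {
    1: {"mono_increasing": 1.0},
    2: {"mono_increasing": 0.5, "nonmono_increasing": 0.5},
    3: {"mono_increasing": 1 / 3, "nonmono_increasing": 1 / 3, "inverted_u": 1 / 3},
    4: {
        "mono_increasing": 0.25,
        "nonmono_increasing": 0.25,
        "inverted_u": 0.25,
        "nonmono_decreasing": 0.25,
    },
    5: {t: 0.2 for t in TRAJECTORY_ORDER},
}

#: Fixed rounded trajectory counts where the exact proportions are non-integer,
#: chosen within +-1 of the exact counts and balanced between the increasing
#: and decreasing trajectory families.  Composition 5 at 6 items alternates the
#: extra item between the two monotone endpoints by trait index.
_COMPOSITION_COUNT_OVERRIDES: Dict[Tuple[int, int], Tuple[Tuple[int, ...], ...]] = {
    (4, 6): ((2, 1, 1, 2, 0),),
    (5, 6): ((2, 1, 1, 1, 1), (1, 1, 1, 1, 2)),
    (5, 12): ((3, 2, 2, 2, 3),),
}

#: Meta-analytic Big Five intercorrelations used as generating trait-pair
#: values, in row-major upper-triangle pair order (1,2), (1,3), ..., (4,5);
#: their assignment to the ten trait pairs is permuted per replication.
TRAIT_PAIR_CORRELATIONS = (0.26, 0.29, 0.36, 0.43, 0.43, 0.36, 0.21, 0.43, 0.20, 0.17)

#: Generating correlations of the faking dimension with traits 1..5.
FAKING_TRAIT_CORRELATIONS = (0.00, 0.10, -0.10, 0.30, -0.30)

#: Generating distribution of category thresholds tau_ik: the intercepts are
#: the negative cumulative sums, gamma_ik = -sum_{m<=k} tau_im with gamma_i0=0.
THRESHOLD_MEANS = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
THRESHOLD_VARIANCE = 0.7

_FAKING_SLOPE_LAWS = {
    "none": (0.0, 0.0),
    "low": (0.0, 0.5),
    "high": (0.25, 0.75),
}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the factorial design (optionally a specific replication)."""

    composition_id: int
    items_per_trait: int
    n_persons: int
    ers_present: bool
    faking_impact: str
    replication: Optional[int] = None

    def __post_init__(self) -> None:
        if self.composition_id not in COMPOSITION_PROPORTIONS:
            raise ValueError(f"composition_id must be 1..5, got {self.composition_id}")
        if self.faking_impact not in _FAKING_SLOPE_LAWS:
            raise ValueError(
                f"faking_impact must be one of {tuple(_FAKING_SLOPE_LAWS)}, "
                f"got {self.faking_impact!r}"
            )
        if self.items_per_trait < 1 or self.n_persons < 1:
            raise ValueError("items_per_trait and n_persons must be positive")

    def label(self) -> str:
        rep = "" if self.replication is None else f"_rep{self.replication:03d}"
        return (
            f"comp{self.composition_id}_i{self.items_per_trait}_n{self.n_persons}"
            f"_ers{int(self.ers_present)}_fak-{self.faking_impact}{rep}"
        )


@dataclass
class TruthManifest:
    """Generating parameters stored alongside each simulated dataset."""

    condition: SimulationCondition
    items: List[ItemParameters]
    persons: PersonParameters
    latent: LatentDistribution
    trajectories: List[str]
    trait_pair_permutation: List[int]
    spec: ModelSpec = field(repr=False, default=None)


def enumerate_design(
    compositions: Sequence[int] = (1, 2, 3, 4, 5),
    items_per_trait: Sequence[int] = (6, 12),
    sample_sizes: Sequence[int] = (500, 1000, 2000),
    ers_levels: Sequence[bool] = (True, False),
    faking_impacts: Sequence[str] = ("none", "low", "high"),
    replications: Optional[int] = None,
) -> List[SimulationCondition]:
    """Enumerate the factorial design (full product: 5*2*3*2*3 = 180 cells).

    With ``replications=None`` one template per cell is returned; with an
    integer, each cell is expanded into that many run descriptors carrying a
    replication index (the study default is 100 datasets per condition).
    """
    cells = [
        SimulationCondition(c, i, n, e, f)
        for c, i, n, e, f in itertools.product(
            compositions, items_per_trait, sample_sizes, ers_levels, faking_impacts
        )
    ]
    if replications is None:
        return cells
    if replications < 1:
        raise ValueError("replications must be positive")
    return [
        SimulationCondition(
            c.composition_id, c.items_per_trait, c.n_persons, c.ers_present,
            c.faking_impact, replication=r,
        )
        for c in cells
        for r in range(replications)
    ]


def build_composition(
    items_per_trait: int, composition_id: int, trait_index: int = 0
) -> List[str]:
    """Trajectory label per item of one trait scale under a composition.

    Non-integer proportions are rounded deterministically so that counts sum to
    ``items_per_trait``, deviate at most one item from the exact fractions, and
    keep the distribution of trajectory families symmetric; the fixed tables
    for the study's scale lengths live in ``_COMPOSITION_COUNT_OVERRIDES`` and
    a largest-remainder rule covers other lengths.
    """
    if composition_id not in COMPOSITION_PROPORTIONS:
        raise ValueError(f"composition_id must be 1..5, got {composition_id}")
    props = COMPOSITION_PROPORTIONS[composition_id]
    exact = np.array([props.get(t, 0.0) * items_per_trait for t in TRAJECTORY_ORDER])
    override = _COMPOSITION_COUNT_OVERRIDES.get((composition_id, items_per_trait))
    if override is not None:
        counts = np.array(override[trait_index % len(override)])
    elif np.allclose(exact, np.round(exact)):
        counts = np.round(exact).astype(int)
    else:
        floors = np.floor(exact).astype(int)
        remainder = exact - floors
        short = items_per_trait - floors.sum()
        # Largest remainder, ties toward the canonical trajectory order.
        order = np.argsort(-remainder, kind="stable")
        counts = floors.copy()
        counts[order[:short]] += 1
    labels: List[str] = []
    for t, c in zip(TRAJECTORY_ORDER, counts):
        labels.extend([t] * int(c))
    assert len(labels) == items_per_trait
    return labels


def make_model_spec(
    items_per_trait: int,
    include_ers: bool = True,
    include_faking: bool = True,
    n_traits: int = N_TRAITS,
    n_categories: int = 7,
) -> ModelSpec:
    """Model specification for ``n_traits`` scales of ``items_per_trait`` items."""
    dims = [Dimension(f"trait{t + 1}", "trait") for t in range(n_traits)]
    if include_ers:
        dims.append(Dimension("ers", "ers"))
    if include_faking:
        dims.append(Dimension("faking", "faking"))
    item_ids, item_trait = [], {}
    for t in range(n_traits):
        for j in range(items_per_trait):
            iid = f"t{t + 1}_i{j + 1:02d}"
            item_ids.append(iid)
            item_trait[iid] = f"trait{t + 1}"
    return ModelSpec(
        n_categories=n_categories,
        dimensions=dims,
        item_ids=item_ids,
        item_trait=item_trait,
    )


def _intercepts_from_thresholds(tau: np.ndarray) -> np.ndarray:
    """gamma_ik = -cumsum(tau) with gamma_i0 = 0 prepended."""
    return np.concatenate([[0.0], -np.cumsum(tau)])


def draw_item_parameters(
    condition: SimulationCondition,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> Tuple[List[ItemParameters], List[str]]:
    """Generating item parameters plus the trajectory label of every item.

    Trait slopes ~ U(0.25, 0.75); ERS slopes ~ N(0.25, 0.1) when ERS is present
    else 0 (no truncation); faking slopes 0 / U(0, 0.5) / U(0.25, 0.75) for
    no/low/high faking impact.  Intercepts come from thresholds drawn around
    equally spaced means with variance 0.7.  Scoring weights are the fixed
    trait / ERS / trajectory-prototype vectors.
    """
    k1 = spec.n_categories
    d = spec.n_dimensions
    trait_w = prototype_weights("trait", k1).array
    ers_w = prototype_weights("ers", k1).array if spec.ers_index is not None else None
    lo, hi = _FAKING_SLOPE_LAWS[condition.faking_impact]

    trajectories: List[str] = []
    per_trait = {
        t: build_composition(condition.items_per_trait, condition.composition_id, ti)
        for ti, t in enumerate(sorted({spec.item_trait[i] for i in spec.item_ids}))
    }
    counters = {t: 0 for t in per_trait}

    items: List[ItemParameters] = []
    for iid in spec.item_ids:
        trait = spec.item_trait[iid]
        trajectory = per_trait[trait][counters[trait]]
        counters[trait] += 1
        trajectories.append(trajectory)

        slopes = np.zeros(d)
        weights = np.zeros((d, k1))
        ti = spec.dimension_index(trait)
        slopes[ti] = rng.uniform(0.25, 0.75)
        weights[ti] = trait_w
        if spec.ers_index is not None:
            ei = spec.ers_index
            slopes[ei] = rng.normal(0.25, 0.1) if condition.ers_present else 0.0
            weights[ei] = ers_w
        if spec.faking_index is not None:
            fi = spec.faking_index
            slopes[fi] = 0.0 if hi == 0.0 else rng.uniform(lo, hi)
            weights[fi] = np.asarray(FAKING_PROTOTYPES[trajectory])
        tau = rng.normal(THRESHOLD_MEANS, np.sqrt(THRESHOLD_VARIANCE))
        items.append(
            ItemParameters(
                slopes=slopes,
                intercepts=_intercepts_from_thresholds(tau),
                scoring_weights=weights,
                item_id=iid,
            )
        )
    return items, trajectories


def _assemble_sigma(pair_values: np.ndarray, include_ers: bool, include_faking: bool) -> np.ndarray:
    """Build the generating latent correlation matrix from permuted pair values."""
    d = N_TRAITS + int(include_ers) + int(include_faking)
    sigma = np.eye(d)
    iu = np.triu_indices(N_TRAITS, k=1)
    sigma[iu] = pair_values
    sigma[(iu[1], iu[0])] = pair_values
    if include_faking:
        fi = d - 1
        sigma[fi, :N_TRAITS] = FAKING_TRAIT_CORRELATIONS
        sigma[:N_TRAITS, fi] = FAKING_TRAIT_CORRELATIONS
    return sigma


def draw_trait_pair_sigma(
    rng: np.random.Generator,
    include_ers: bool = True,
    include_faking: bool = True,
    max_retries: int = 100,
) -> Tuple[LatentDistribution, List[int]]:
    """Generating Sigma with trait-pair correlations randomly assigned to pairs.

    The ten meta-analytic values are permuted over the ten trait pairs; if the
    permuted matrix (with the fixed faking and ERS rows) is not positive
    definite, a new permutation is drawn, up to ``max_retries`` times.
    """
    values = np.asarray(TRAIT_PAIR_CORRELATIONS)
    for _ in range(max_retries):
        perm = rng.permutation(len(values))
        sigma = _assemble_sigma(values[perm], include_ers, include_faking)
        if float(np.linalg.eigvalsh(sigma).min()) > 1e-8:
            latent = LatentDistribution(mean=np.zeros(sigma.shape[0]), covariance=sigma)
            return latent, perm.tolist()
    raise RuntimeError(
        f"no positive-definite trait-pair assignment found in {max_retries} draws"
    )


def draw_persons(
    n: int, latent: LatentDistribution, rng: np.random.Generator
) -> PersonParameters:
    """Draw N person-parameter vectors from MVN(mean, covariance)."""
    latent.assert_positive_definite()
    values = rng.multivariate_normal(
        latent.mean, latent.covariance, size=n, method="cholesky"
    )
    return PersonParameters(values=values)


def sample_responses(
    persons: PersonParameters,
    items: Sequence[ItemParameters],
    rng: np.random.Generator,
    item_ids: Optional[List[str]] = None,
) -> ResponseMatrix:
    """Draw one categorical response per person-item cell from the MNRM."""
    b, gamma = stack_loading_matrices(items)
    if persons.n_dimensions != b.shape[0]:
        raise ValueError("persons and items disagree on the number of dimensions")
    lp = all_log_probabilities(persons.values, b, gamma)
    cum = np.cumsum(np.exp(lp), axis=-1)
    u = rng.random(size=cum.shape[:2])
    draws = (cum < u[:, :, None]).sum(axis=-1)
    k1 = gamma.shape[1]
    np.clip(draws, 0, k1 - 1, out=draws)
    ids = item_ids or [it.item_id or f"item{j + 1:03d}" for j, it in enumerate(items)]
    return ResponseMatrix(values=draws, item_ids=ids)


def _condition_seed_sequence(
    master_seed: int, condition: SimulationCondition
) -> np.random.SeedSequence:
    """Hierarchical seeding: master seed -> condition cell -> replication."""
    key = (
        condition.composition_id,
        condition.items_per_trait,
        condition.n_persons,
        int(condition.ers_present),
        ("none", "low", "high").index(condition.faking_impact),
        condition.replication or 0,
    )
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def simulate_dataset(
    condition: SimulationCondition,
    master_seed: int = 0,
) -> Tuple[ResponseMatrix, TruthManifest]:
    """Generate one replication: spec, truth parameters, and responses.

    Identical (condition, replication, master seed) triples yield bit-identical
    output.  The generating model always carries all seven dimensions (five
    traits, ERS, faking); absent factors simply have zero slopes.
    """
    rng = np.random.default_rng(_condition_seed_sequence(master_seed, condition))
    spec = make_model_spec(condition.items_per_trait)
    items, trajectories = draw_item_parameters(condition, spec, rng)
    latent, perm = draw_trait_pair_sigma(rng)
    persons = draw_persons(condition.n_persons, latent, rng)
    responses = sample_responses(persons, items, rng, item_ids=list(spec.item_ids))
    manifest = TruthManifest(
        condition=condition,
        items=items,
        persons=persons,
        latent=latent,
        trajectories=trajectories,
        trait_pair_permutation=perm,
        spec=spec,
    )
    return responses, manifest
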