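"""Deterministic small datasets used throughout the test suites and examples."""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .desirability import RatingHistogram
from .model import (
    Dimension,
    ItemParameters,
    LatentDistribution,
    ModelSpec,
)
from .simulate import draw_persons, sample_responses
from .weights import FAKING_PROTOTYPES, TRAJECTORY_ORDER, prototype_weights

__all__ = ["fixture_generator", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("tiny_gpcm", "two_dim_faking", "rating_histograms", "anova_fixture")


def _gpcm_bundle(seed: int):
    """200 persons x 6 items, one trait dimension (a GPCM)."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(
        n_categories=7,
        dimensions=[Dimension("trait1", "trait")],
        item_ids=[f"g_i{j + 1}" for j in range(6)],
        item_trait={f"g_i{j + 1}": "trait1" for j in range(6)},
    )
    trait_w = prototype_weights("trait", 7).array
    items = []
    for iid in spec.item_ids:
        tau = rng.normal((-1.5, -0.9, -0.3, 0.3, 0.9, 1.5), np.sqrt(0.7))
        items.append(
            ItemParameters(
                slopes=np.array([rng.uniform(0.25, 0.75)]),
                intercepts=np.concatenate([[0.0], -np.cumsum(tau)]),
                scoring_weights=trait_w[None, :],
                item_id=iid,
            )
        )
    latent = LatentDistribution(mean=np.zeros(1), covariance=np.eye(1))
    persons = draw_persons(200, latent, rng)
    responses = sample_responses(persons, items, rng, item_ids=list(spec.item_ids))
    return spec, items, latent, persons, responses


def _two_dim_faking_bundle(seed: int):
    """One trait plus a faking dimension with distinct weight vectors."""
    rng = np.random.default_rng(seed)
    item_ids = [f"f_i{j + 1}" for j in range(6)]
    spec = ModelSpec(
        n_categories=7,
        dimensions=[Dimension("trait1", "trait"), Dimension("faking", "faking")],
        item_ids=item_ids,
        item_trait={i: "trait1" for i in item_ids},
    )
    trait_w = prototype_weights("trait", 7).array
    trajectories = ["inverted_u", "nonmono_increasing", "inverted_u",
                    "nonmono_decreasing", "inverted_u", "nonmono_increasing"]
    items = []
    for iid, traj in zip(item_ids, trajectories):
        tau = rng.normal((-1.5, -0.9, -0.3, 0.3, 0.9, 1.5), np.sqrt(0.7))
        items.append(
            ItemParameters(
                slopes=np.array([rng.uniform(0.4, 0.75), rng.uniform(0.3, 0.6)]),
                intercepts=np.concatenate([[0.0], -np.cumsum(tau)]),
                scoring_weights=np.stack([trait_w, np.asarray(FAKING_PROTOTYPES[traj])]),
                item_id=iid,
            )
        )
    latent = LatentDistribution(
        mean=np.zeros(2), covariance=np.array([[1.0, 0.3], [0.3, 1.0]])
    )
    persons = draw_persons(1000, latent, rng)
    responses = sample_responses(persons, items, rng, item_ids=item_ids)
    return spec, items, latent, persons, responses, trajectories


def _rating_histograms(seed: int) -> List[RatingHistogram]:
    """Five histograms, one drawn around each trajectory prototype (n=152)."""
    rng = np.random.default_rng(seed)
    out = []
    for t in TRAJECTORY_ORDER:
        w = np.asarray(FAKING_PROTOTYPES[t])
        p = w / w.sum()
        counts = rng.multinomial(152, p)
        out.append(RatingHistogram(item_id=f"pilot_{t}", counts=tuple(counts)))
    return out


def _anova_fixture(seed: int) -> pd.DataFrame:
    """16-row balanced 2x2 between x 2-level repeated-measures table."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in (0, 1):
        for b in (0, 1):
            for rep in range(2):
                base = 0.5 * a - 0.3 * b + rng.normal(0, 0.1)
                for model in ("m0", "m1"):
                    rows.append(
                        {
                            "A": a,
                            "B": b,
                            "replication": rep,
                            "model": model,
                            "y": base + (0.4 if model == "m1" else 0.0)
                            + rng.normal(0, 0.05),
                        }
                    )
    return pd.DataFrame(rows)


def fixture_generator(kind: str, seed: int = 0):
    """Return the deterministic fixture bundle named ``kind``."""
    if kind == "tiny_gpcm":
        return _gpcm_bundle(seed)
    if kind == "two_dim_faking":
        return _two_dim_faking_bundle(seed)
    if kind == "rating_histograms":
        return _rating_histograms(seed)
    if kind == "anova_fixture":
        return _anova_fixture(seed)
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
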