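"""Classification of item desirability-rating histograms into trajectory types.

Pilot-study raters judge which response category of an item is most desirable
in a given assessment context; the resulting per-item histogram of ratings is
classified into one of five prototypical desirability trajectories by a
minimal Pearson X² rule: expected frequencies under each prototype are
proportional to the prototype's scoring weights, and the type with the
smallest X² wins.  The same histograms also yield empirical faking scoring
weights (relative rating frequencies rescaled to the common 0..6 metric).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np

from .weights import (
    FAKING_PROTOTYPES,
    TRAJECTORY_ORDER,
    WeightVector,
    rescale_common_metric,
)

__all__ = [
    "RatingHistogram",
    "TrajectoryClassification",
    "recode_negative_keying",
    "classify_trajectory",
    "empirical_faking_weights",
]

#: Substitute expected frequency for cells where the prototype weight is zero
#: but observed ratings occur (keeps X² finite; exact-prototype histograms
#: still attain X² = 0 because empty-expected empty-observed cells contribute
#: nothing in the continuity limit).
ZERO_CELL_FLOOR = 0.5


@dataclass(frozen=True)
class RatingHistogram:
    """Counts of desirability ratings per response category for one item."""

    item_id: str
    counts: Tuple[int, ...]
    keying: str = "positive"

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("counts must be a 1-D vector of length K+1")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if self.keying not in ("positive", "negative"):
            raise ValueError("keying must be 'positive' or 'negative'")
        object.__setattr__(self, "counts", tuple(int(c) for c in arr))

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TrajectoryClassification:
    """X² per trajectory type, the winning type, and the expectations used."""

    item_id: str
    x2: Dict[str, float]
    assigned: str
    expected: Dict[str, Tuple[float, ...]]


def recode_negative_keying(h: RatingHistogram) -> RatingHistogram:
    """Reverse the category order of negatively keyed items (involution)."""
    if h.keying == "positive":
        return h
    return replace(h, counts=tuple(reversed(h.counts)), keying="positive")


def _pearson_x2(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson X² with zero-expected cells handled by the continuity rule."""
    x2 = 0.0
    for o, e in zip(observed, expected):
        if e == 0.0:
            if o == 0.0:
                continue
            e = ZERO_CELL_FLOOR
        x2 += (o - e) ** 2 / e
    return x2


def classify_trajectory(h: RatingHistogram) -> TrajectoryClassification:
    """Assign the desirability trajectory type minimizing Pearson's X².

    Expected frequencies under type t are E_tk = n * w_tk / sum_k w_tk with
    w the prototype scoring-weight vector.  Ties in the minimum break toward
    the earlier type in the canonical trajectory order.  Requires positive
    total count and seven categories (the prototypes' scale length).
    """
    if h.n <= 0:
        raise ValueError("histogram has no ratings")
    obs = h.array
    if obs.size != 7:
        raise ValueError("trajectory prototypes are defined for seven categories")
    x2: Dict[str, float] = {}
    expected: Dict[str, Tuple[float, ...]] = {}
    for t in TRAJECTORY_ORDER:
        w = np.asarray(FAKING_PROTOTYPES[t])
        e = h.n * w / w.sum()
        expected[t] = tuple(e)
        x2[t] = _pearson_x2(obs, e)
    assigned = min(TRAJECTORY_ORDER, key=lambda t: (x2[t], TRAJECTORY_ORDER.index(t)))
    return TrajectoryClassification(
        item_id=h.item_id, x2=x2, assigned=assigned, expected=expected
    )


def empirical_faking_weights(h: RatingHistogram) -> WeightVector:
    """Faking scoring weights from rating relative frequencies, on 0..6.

    The relative frequency per category is rescaled so the least desirable
    category gets weight 0 and the most desirable weight 6.  A perfectly
    uniform histogram carries no desirability information and raises a
    degenerate-input error (via the rescaler).
    """
    if h.n <= 0:
        raise ValueError("histogram has no ratings")
    rel = h.array / h.n
    raw = WeightVector(tuple(rel), "faking")
    return rescale_common_metric(raw)
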