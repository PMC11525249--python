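"""Scoring-weight vectors for trait, extreme-response-style, and faking dimensions.

Scoring weights are fixed a priori (never estimated) and code how strongly each
response category of an item expresses a latent dimension.  Substantive traits
use equally spaced weights (0..K); extreme response style (ERS) loads on the two
endpoint categories; the faking dimension uses one of five prototypical
desirability trajectories describing how social desirability varies over a
seven-point rating scale.  All weights live on a common 0..6 metric so that
slope parameters are comparable across dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "TRAJECTORY_ORDER",
    "FAKING_PROTOTYPES",
    "WeightVector",
    "DegenerateWeightsError",
    "prototype_weights",
    "rescale_common_metric",
    "contaminate_weights",
]

#: Canonical order of the five desirability trajectory types (also the
#: tie-breaking order for classification).
TRAJECTORY_ORDER = (
    "mono_increasing",
    "nonmono_increasing",
    "inverted_u",
    "nonmono_decreasing",
    "mono_decreasing",
)

#: Prototype faking scoring-weight vectors for a seven-point scale, one per
#: desirability trajectory type.  Increasing/decreasing pairs are mirror images.
FAKING_PROTOTYPES = {
    "mono_increasing": (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    "nonmono_increasing": (0.0, 1.5, 3.0, 4.5, 6.0, 6.0, 4.5),
    "inverted_u": (0.0, 2.0, 4.0, 6.0, 4.0, 2.0, 0.0),
    "nonmono_decreasing": (4.5, 6.0, 6.0, 4.5, 3.0, 1.5, 0.0),
    "mono_decreasing": (6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.0),
}

#: Common metric bounds after rescaling.
METRIC_MAX = 6.0


class DegenerateWeightsError(ValueError):
    """Raised when a weight vector is constant and cannot be rescaled."""


@dataclass(frozen=True)
class WeightVector:
    """A length-(K+1) scoring-weight vector on the common 0..6 metric.

    Parameters
    ----------
    values
        Weight per response category, ``values[k]`` for category ``k``.
    role
        Which kind of dimension the vector scores: ``"trait"``, ``"ers"``,
        or ``"faking"``.
    trajectory
        For faking vectors, the desirability trajectory label.
    """

    values: tuple
    role: str
    trajectory: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("weight vector must be 1-D with at least two entries")
        if not np.all(np.isfinite(arr)):
            raise ValueError("weight vector contains non-finite entries")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def n_categories(self) -> int:
        return len(self.values)


def prototype_weights(kind: str, n_categories: int) -> WeightVector:
    """Return the published prototype weight vector for ``kind``.

    ``kind`` is ``"trait"``, ``"ers"``, or ``"faking:<trajectory>"`` where
    ``<trajectory>`` is one of :data:`TRAJECTORY_ORDER`.  Trait weights are the
    equally spaced values 0..K; ERS weights indicate the two endpoint
    categories, rescaled to the common metric; faking prototypes are defined
    for seven-point scales only.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be at least 2")
    if kind == "trait":
        return WeightVector(tuple(float(k) for k in range(n_categories)), "trait")
    if kind == "ers":
        raw = np.zeros(n_categories)
        raw[0] = raw[-1] = 1.0
        vec = rescale_common_metric(WeightVector(tuple(raw), "ers"))
        return vec
    if kind.startswith("faking:"):
        trajectory = kind.split(":", 1)[1]
        if trajectory not in FAKING_PROTOTYPES:
            raise ValueError(
                f"unknown trajectory {trajectory!r}; expected one of {TRAJECTORY_ORDER}"
            )
        if n_categories != 7:
            raise ValueError(
                "faking prototypes are defined for seven-point scales only "
                f"(got n_categories={n_categories})"
            )
        return WeightVector(FAKING_PROTOTYPES[trajectory], "faking", trajectory)
    raise ValueError(f"unknown weight kind {kind!r}")


def rescale_common_metric(w: WeightVector) -> WeightVector:
    """Affinely map ``w`` so its minimum is 0 and maximum is :data:`METRIC_MAX`.

    The map preserves the ordering (shape) of the weights; it is idempotent for
    vectors already on the common metric.  A constant vector has no defined
    rescaling and raises :class:`DegenerateWeightsError`.
    """
    arr = w.array
    lo, hi = arr.min(), arr.max()
    if hi - lo <= 0.0:
        raise DegenerateWeightsError("constant weight vector cannot be rescaled")
    scaled = (arr - lo) * (METRIC_MAX / (hi - lo))
    return replace(w, values=tuple(scaled))


def contaminate_weights(
    w: WeightVector,
    noise_scale: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> WeightVector:
    """Perturb weights with additive uniform noise, clipped to [0, 6].

    Emulates that faking scoring weights used for estimation are only
    approximations (e.g., from pilot-study ratings) of the weights that
    generated the data.  Noise is i.i.d. U(−noise_scale, +noise_scale) per
    weight; ``noise_scale=0`` returns the input unchanged.  Reproducible for a
    fixed ``seed``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    if noise_scale == 0:
        return w
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.uniform(-noise_scale, noise_scale, size=w.n_categories)
    values = np.clip(w.array + noise, 0.0, METRIC_MAX)
    return replace(w, values=tuple(values))
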