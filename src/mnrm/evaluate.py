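"""Recovery statistics and effect-size analyses for simulation output, plus
the low-stakes / high-stakes (LS/HS) empirical comparison statistics.

Person-parameter recovery is summarized by Fisher-z transformed Pearson
correlations between estimated and true latent trait scores (aggregated as the
back-transformed mean).  Latent-correlation recovery uses the per-replication
mean deviation over the ten substantive trait pairs (bias) and its root mean
square (RMSE).  Factorial simulation results are summarized with generalized
eta-squared effect sizes from a mixed ANOVA in which the fitted model is a
repeated-measures factor (both models see the same data within a replication).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PersonRecovery",
    "person_recovery",
    "correlation_bias",
    "correlation_rmse",
    "generalized_eta_squared",
    "mean_shift_by_trajectory",
    "compare_dependent_correlations",
]

#: Cap applied to |r| before atanh so that perfect correlations stay finite.
_R_CAP = 1.0 - 1e-12


@dataclass
class PersonRecovery:
    """Per-trait recovery correlations and their Fisher-z aggregate."""

    correlations: np.ndarray
    fisher_z: np.ndarray
    mean_back_transformed: float


def person_recovery(theta_hat: np.ndarray, theta_true: np.ndarray) -> PersonRecovery:
    """Correlation between estimated and true person parameters, per trait.

    Columns are traits.  Each correlation is Fisher-z transformed
    (z = atanh(r)); the aggregate is the back-transformed mean tanh(mean z).
    Perfect correlations are capped at 1 - 1e-12 before the transform.
    """
    theta_hat = np.atleast_2d(np.asarray(theta_hat, dtype=float))
    theta_true = np.atleast_2d(np.asarray(theta_true, dtype=float))
    if theta_hat.shape != theta_true.shape:
        raise ValueError("theta_hat and theta_true must have identical shapes")
    sds_hat = theta_hat.std(axis=0)
    sds_true = theta_true.std(axis=0)
    if np.any(sds_hat == 0) or np.any(sds_true == 0):
        raise ValueError("zero-variance column: correlation undefined")
    ctr_hat = theta_hat - theta_hat.mean(axis=0)
    ctr_true = theta_true - theta_true.mean(axis=0)
    r = (ctr_hat * ctr_true).mean(axis=0) / (sds_hat * sds_true)
    r = np.clip(r, -_R_CAP, _R_CAP)
    z = np.arctanh(r)
    return PersonRecovery(
        correlations=r, fisher_z=z, mean_back_transformed=float(np.tanh(z.mean()))
    )


def _trait_pair_deviation(
    sigma_hat: np.ndarray, sigma_true: np.ndarray, n_traits: int
) -> np.ndarray:
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    sigma_true = np.asarray(sigma_true, dtype=float)
    if sigma_hat.shape[0] < n_traits or sigma_true.shape[0] < n_traits:
        raise ValueError(f"correlation matrices must cover {n_traits} traits")
    iu = np.triu_indices(n_traits, k=1)
    return sigma_hat[:n_traits, :n_traits][iu] - sigma_true[:n_traits, :n_traits][iu]


def correlation_bias(
    sigma_hat: np.ndarray, sigma_true: np.ndarray, n_traits: int = 5
) -> float:
    """Mean deviation rho-hat minus rho over the substantive trait pairs."""
    return float(_trait_pair_deviation(sigma_hat, sigma_true, n_traits).mean())


def correlation_rmse(
    sigma_hat: np.ndarray, sigma_true: np.ndarray, n_traits: int = 5
) -> float:
    """Root mean squared deviation over the substantive trait pairs."""
    dev = _trait_pair_deviation(sigma_hat, sigma_true, n_traits)
    return float(np.sqrt((dev ** 2).mean()))


# ---------------------------------------------------------------------------
# Generalized eta squared (mixed ANOVA, balanced designs)
# ---------------------------------------------------------------------------


def _effect_ss(
    table: pd.DataFrame, dv: str, factors: Sequence[str], cache: Dict[Tuple[str, ...], float]
) -> float:
    """Sum of squares of one effect in a balanced design via inclusion-exclusion."""

    def uncorrected(subset: Tuple[str, ...]) -> float:
        if subset in cache:
            return cache[subset]
        if not subset:
            val = table[dv].sum() ** 2 / len(table)
        else:
            grp = table.groupby(list(subset), observed=True)[dv]
            val = float((grp.sum() ** 2 / grp.size()).sum())
        cache[subset] = val
        return val

    total = 0.0
    for r in range(len(factors) + 1):
        for sub in itertools.combinations(sorted(factors), r):
            total += (-1) ** (len(factors) - len(sub)) * uncorrected(sub)
    return total


def generalized_eta_squared(
    table: pd.DataFrame,
    dv: str,
    between: Sequence[str],
    within: Optional[str] = None,
    subject: str = "replication",
) -> pd.Series:
    """Generalized eta-squared for every effect of a balanced mixed design.

    ``between`` are manipulated between-subject factors (here: the simulation
    factors), ``within`` the repeated-measures factor (the fitted model), and
    ``subject`` identifies the observational unit within each between cell
    (here: the replication).  Because every design factor is manipulated, the
    generalized eta-squared denominator contains the effect itself plus all
    subject-related variance strata: SS_effect / (SS_effect + SS_subjects +
    SS_within_residual).  Without a within factor this reduces to the
    classical eta-squared SS_effect / (SS_effect + SS_error).

    Returns a Series indexed by effect name ("A", "A:B", ..., and
    "model"-crossed terms when ``within`` is given).
    """
    work = table.copy()
    work["_subj"] = (
        work[list(between)].astype(str).agg("|".join, axis=1)
        + "|"
        + work[subject].astype(str)
    )
    counts = work.groupby(list(between), observed=True)[dv].size()
    n_expected_cells = int(np.prod([work[f].nunique() for f in between]))
    if len(counts) != n_expected_cells:
        present = set(counts.index)
        levels = [sorted(work[f].unique()) for f in between]
        missing_cells = [
            c for c in itertools.product(*levels)
            if (c if len(c) > 1 else c[0]) not in present
        ]
        raise ValueError(f"missing design cells: {missing_cells}")
    if counts.nunique() > 1:
        unbalanced = counts[counts != counts.max()]
        raise ValueError(f"unbalanced or missing cells: {unbalanced.to_dict()}")

    cache: Dict[Tuple[str, ...], float] = {}
    effects: Dict[str, float] = {}
    for r in range(1, len(between) + 1):
        for sub in itertools.combinations(sorted(between), r):
            effects[":".join(sub)] = _effect_ss(work, dv, sub, cache)
    ss_total = float((work[dv] ** 2).sum()) - work[dv].sum() ** 2 / len(work)

    if within is None:
        ss_error = ss_total - sum(effects.values())
        denom_extra = max(ss_error, 0.0)
    else:
        for r in range(0, len(between) + 1):
            for sub in itertools.combinations(sorted(between), r):
                name = ":".join(sub + (within,)) if sub else within
                effects[name] = _effect_ss(work, dv, sub + (within,), cache)
        # Between-subject error stratum: subjects within between cells.
        grp_subj = work.groupby("_subj", observed=True)[dv]
        t_subj = float((grp_subj.sum() ** 2 / grp_subj.size()).sum())
        grp_cells = work.groupby(list(between), observed=True)[dv]
        t_between = float((grp_cells.sum() ** 2 / grp_cells.size()).sum())
        ss_subj = t_subj - t_between
        ss_resid = ss_total - sum(effects.values()) - ss_subj
        denom_extra = max(ss_subj, 0.0) + max(ss_resid, 0.0)

    out = {}
    for name, ss in effects.items():
        ss = max(ss, 0.0)
        denom = ss + denom_extra
        out[name] = 0.0 if denom <= 0 else ss / denom
    return pd.Series(out, name="eta2_g")


# ---------------------------------------------------------------------------
# LS/HS empirical comparison statistics
# ---------------------------------------------------------------------------


def mean_shift_by_trajectory(
    ls_responses: np.ndarray,
    hs_responses: np.ndarray,
    trajectories: Sequence[str],
) -> Dict[str, float]:
    """Mean HS-minus-LS item-score shift per desirability trajectory type.

    Responses are 0-based categories from the same persons and items under the
    low-stakes and high-stakes conditions (negatively keyed items recoded
    upstream); shifts are reported in rating-scale points and are identical on
    the 0..K and 1..K+1 metrics.
    """
    ls = np.asarray(ls_responses, dtype=float)
    hs = np.asarray(hs_responses, dtype=float)
    if ls.shape != hs.shape:
        raise ValueError("LS and HS response matrices must have identical shapes")
    if ls.shape[1] != len(trajectories):
        raise ValueError("one trajectory label per item is required")
    shift = hs.mean(axis=0) - ls.mean(axis=0)
    labels = np.asarray(list(trajectories))
    return {
        t: float(shift[labels == t].mean()) for t in dict.fromkeys(trajectories)
    }


def compare_dependent_correlations(
    r_with: float, r_without: float, r_between: float, n: int
) -> Dict[str, float]:
    """Steiger's Z test for two dependent correlations sharing one variable.

    ``r_with`` and ``r_without`` both involve the shared variable (here: the
    LS trait score correlated with the two HS trait scores), ``r_between`` is
    the correlation between the two non-shared variables.  One-tailed p for
    the alternative ``r_with > r_without``.
    """
    for name, r in (("r_with", r_with), ("r_without", r_without), ("r_between", r_between)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1 = math.atanh(r_with)
    z2 = math.atanh(r_without)
    rbar = 0.5 * (r_with + r_without)
    rbar2 = rbar * rbar
    s = (r_between * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r_between ** 2)) / (
        (1 - rbar2) ** 2
    )
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * s))
    return {
        "statistic": z,
        "p_one_tailed": float(stats.norm.sf(z)),
        "p_two_tailed": float(2 * stats.norm.sf(abs(z))),
    }
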