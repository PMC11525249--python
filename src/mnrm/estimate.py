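"""Marginal maximum-likelihood estimation of MNRM variants.

Two fitting routes are provided.  The workhorse is a Metropolis-Hastings
Robbins-Monro (MH-RM) stochastic-approximation algorithm suitable for the
high-dimensional models of interest (five traits + ERS + faking): each cycle
imputes latent scores by a few Metropolis-Hastings random-walk steps, takes a
damped per-item Newton step on the complete-data multinomial-logistic
log-likelihood with a Robbins-Monro gain, and updates the latent covariance by
a gain-smoothed moment estimate followed by the exact
rescale-to-correlation/slope-compensation identification transform.  The
second route, a Gauss-Hermite quadrature EM (generalized EM for the latent
correlations), is exact up to quadrature error and serves as a low-dimensional
oracle (D <= 4).

Scoring weights are fixed a priori; the free parameters are item slopes (one
per loaded dimension), category intercepts (k >= 1), and all pairwise latent
correlations.  Person scores are maximum a-posteriori (MAP) modes under the
estimated multivariate-normal latent distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .model import (
    MISSING,
    ItemParameters,
    LatentDistribution,
    ModelSpec,
    ModelStructureError,
    PersonParameters,
    ResponseMatrix,
)
from .weights import FAKING_PROTOTYPES, contaminate_weights, prototype_weights, WeightVector

__all__ = [
    "FitOptions",
    "FitResult",
    "SelectionResult",
    "fit",
    "score_map",
    "compare_models",
    "anchored_item_selection",
    "count_free_parameters",
    "build_weight_matrices",
]


@dataclass
class FitOptions:
    """Settings for :func:`fit` (artifact plumbing, not part of the model).

    ``algorithm`` is ``"mhrm"`` or ``"em_quadrature"`` (the latter permitted
    for D <= 4 only).  MH-RM defaults: 150 burn-in cycles, 5 MH draws per
    cycle, Robbins-Monro gain 1/j afterwards, convergence when the maximum
    parameter change stays below ``tol`` for ``window`` consecutive cycles.
    """

    algorithm: str = "mhrm"
    n_burnin: int = 150
    mh_draws: int = 5
    gain_decay: float = 1.0
    tol: float = 1e-3
    window: int = 3
    max_cycles: int = 2000
    quad_nodes: int = 21
    seed: Optional[int] = None
    loglik_mc_draws: int = 1000

    def __post_init__(self) -> None:
        if self.algorithm not in ("mhrm", "em_quadrature"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class FitResult:
    """Estimated item parameters, latent correlations, and diagnostics."""

    spec: ModelSpec
    items: List[ItemParameters]
    sigma: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    n_cycles: int
    algorithm: str
    trace: List[float] = field(default_factory=list, repr=False)
    options: Optional[FitOptions] = field(default=None, repr=False)

    @property
    def latent(self) -> LatentDistribution:
        return LatentDistribution(
            mean=np.zeros(self.sigma.shape[0]), covariance=self.sigma
        )

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n_obs)


def count_free_parameters(spec: ModelSpec, n_frozen_slopes: int = 0) -> int:
    """Free-parameter bookkeeping: slopes + intercepts (k>=1) + correlations.

    Every item contributes one slope per loaded dimension (its trait plus each
    bias dimension in the spec) and K intercepts; all D(D-1)/2 latent
    correlations are freely estimated.
    """
    i = spec.n_items
    k = spec.n_categories - 1
    d = spec.n_dimensions
    n_slopes = i * (1 + len(spec.bias_indices)) - n_frozen_slopes
    return n_slopes + i * k + d * (d - 1) // 2


def build_weight_matrices(
    spec: ModelSpec,
    trajectories: Union[Mapping[str, str], Sequence[str], None] = None,
    faking_weights: Optional[Mapping[str, np.ndarray]] = None,
    noise_scale: float = 0.0,
    seed: Optional[int] = None,
) -> List[np.ndarray]:
    """Fixed D x (K+1) scoring-weight matrix per item of ``spec``.

    Trait rows are the equally spaced 0..K weights, the ERS row the rescaled
    endpoint indicator.  The faking row comes either from the trajectory
    prototype per item (``trajectories``) or from explicit per-item vectors
    (``faking_weights``, e.g. empirical pilot-study weights).  ``noise_scale``
    contaminates the faking rows with uniform noise to emulate that the
    weights used for estimation only approximate the generating ones.
    """
    k1 = spec.n_categories
    trait_w = prototype_weights("trait", k1).array
    ers_w = prototype_weights("ers", k1).array if spec.ers_index is not None else None
    if isinstance(trajectories, Sequence) and not isinstance(trajectories, str):
        trajectories = dict(zip(spec.item_ids, trajectories))
    rng = np.random.default_rng(seed)
    mats: List[np.ndarray] = []
    for iid in spec.item_ids:
        w = np.zeros((spec.n_dimensions, k1))
        w[spec.dimension_index(spec.item_trait[iid])] = trait_w
        if spec.ers_index is not None:
            w[spec.ers_index] = ers_w
        if spec.faking_index is not None:
            if faking_weights is not None:
                fw = np.asarray(faking_weights[iid], dtype=float)
            elif trajectories is not None:
                fw = np.asarray(FAKING_PROTOTYPES[trajectories[iid]])
            else:
                raise ValueError(
                    "faking dimension present: provide trajectories or faking_weights"
                )
            if noise_scale > 0:
                fw = contaminate_weights(
                    WeightVector(tuple(fw), "faking"), noise_scale, rng
                ).array
            w[spec.faking_index] = fw
        mats.append(w)
    return mats


# ---------------------------------------------------------------------------
# Shared workspace
# ---------------------------------------------------------------------------


class _Workspace:
    """Aligned arrays and current parameter state for one fit."""

    def __init__(
        self,
        responses: ResponseMatrix,
        spec: ModelSpec,
        weights: Union[Sequence[np.ndarray], Mapping[str, np.ndarray]],
        frozen_slopes: Optional[Mapping[str, Mapping[str, float]]] = None,
    ) -> None:
        self.spec = spec
        if isinstance(weights, Mapping):
            weights = [np.asarray(weights[i]) for i in spec.item_ids]
        else:
            weights = [np.asarray(w) for w in weights]
        if len(weights) != spec.n_items:
            raise ModelStructureError("one weight matrix per item is required")

        # Align response columns with the spec's item order.
        if responses.item_ids != spec.item_ids:
            try:
                order = [responses.item_ids.index(i) for i in spec.item_ids]
            except ValueError as exc:
                raise ModelStructureError(
                    "responses are missing items required by the spec"
                ) from exc
            y = responses.values[:, order]
        else:
            y = responses.values
        responses.validate_categories(spec.n_categories)
        self.Y = np.ascontiguousarray(y)
        self.obs = self.Y != MISSING
        self._has_missing = not bool(self.obs.all())
        self.Ysafe = np.where(self.obs, self.Y, 0)
        self._cache = None
        self.N, self.I = self.Y.shape
        self.D = spec.n_dimensions
        self.K1 = spec.n_categories

        loaded = [spec.loaded_dimensions(iid) for iid in spec.item_ids]
        self.load_idx = np.asarray(loaded)  # (I, P_s)
        self.P_s = self.load_idx.shape[1]
        self.S_load = np.stack(
            [weights[i][self.load_idx[i]] for i in range(self.I)]
        )  # (I, P_s, K1)
        self.weights = weights

        # Trait slopes start mid-scale; bias-dimension (ERS/faking) slopes
        # start small so that, under weight collinearity, spurious bias
        # loadings are not baked in from the start.
        self.alpha = np.full((self.I, self.P_s), 0.5)
        self.alpha[:, 1:] = 0.1
        # Column of the faking dimension in the loaded-slope layout, if any.
        self.faking_col: Optional[int] = None
        if spec.faking_index is not None:
            self.faking_col = 1 + spec.bias_indices.index(spec.faking_index)
        counts = np.stack(
            [np.bincount(self.Y[self.obs[:, i], i], minlength=self.K1)
             for i in range(self.I)]
        ).astype(float)
        if np.any(counts == 0):
            warnings.warn(
                "some item categories have zero observed responses; their "
                "intercepts are only weakly determined",
                RuntimeWarning,
            )
        self.gamma = np.log(counts + 0.5)
        self.gamma -= self.gamma[:, [0]]

        self.frozen = np.zeros((self.I, self.P_s), dtype=bool)
        self.n_frozen = 0
        if frozen_slopes:
            for iid, dims in frozen_slopes.items():
                i = spec.item_ids.index(iid)
                for label, value in dims.items():
                    d = spec.dimension_index(label)
                    (pos,) = np.where(self.load_idx[i] == d)
                    if pos.size != 1:
                        raise ModelStructureError(
                            f"item {iid} does not load on dimension {label}"
                        )
                    self.alpha[i, pos[0]] = float(value)
                    self.frozen[i, pos[0]] = True
            self.n_frozen = int(self.frozen.sum())

        self._row_idx = np.arange(self.N)[:, None]
        self._flat_obs = np.arange(self.I)[None, :] * self.K1 + self.Ysafe

    # -- current parameters ------------------------------------------------
    def invalidate(self) -> None:
        self._cache = None

    def loading_tensor(self) -> np.ndarray:
        a = np.zeros((self.I, self.D, self.K1))
        rows = np.arange(self.I)[:, None]
        a[rows, self.load_idx] = self.alpha[:, :, None] * self.S_load
        return a

    def stacked(self) -> Tuple[np.ndarray, np.ndarray]:
        if self._cache is None:
            a = self.loading_tensor()
            b = a.transpose(1, 0, 2).reshape(self.D, self.I * self.K1).copy()
            self._cache = (b, self.gamma.copy())
        return self._cache

    def predictors(self, theta: np.ndarray) -> np.ndarray:
        b, gamma = self.stacked()
        pred = (theta @ b).reshape(theta.shape[0], self.I, self.K1)
        pred += gamma
        return pred

    def log_probs(self, theta: np.ndarray) -> np.ndarray:
        pred = self.predictors(theta)
        m = pred.max(axis=-1, keepdims=True)
        pred -= m
        np.exp(pred, out=pred)
        s = pred.sum(axis=-1, keepdims=True)
        np.log(pred, out=pred)
        pred -= np.log(s)
        return pred

    def probs(self, theta: np.ndarray) -> np.ndarray:
        pred = self.predictors(theta)
        pred -= pred.max(axis=-1, keepdims=True)
        np.exp(pred, out=pred)
        pred /= pred.sum(axis=-1, keepdims=True)
        return pred

    def person_loglik(self, theta: np.ndarray) -> np.ndarray:
        pred = self.predictors(theta)
        obs_pred = pred.reshape(self.N, self.I * self.K1)[self._row_idx, self._flat_obs]
        m = pred.max(axis=-1)
        pred -= m[:, :, None]
        np.exp(pred, out=pred)
        cell = obs_pred - m - np.log(pred.sum(axis=-1))
        if self._has_missing:
            cell = np.where(self.obs, cell, 0.0)
        return cell.sum(axis=1)

    def as_items(self) -> List[ItemParameters]:
        items = []
        for i, iid in enumerate(self.spec.item_ids):
            slopes = np.zeros(self.D)
            slopes[self.load_idx[i]] = self.alpha[i]
            items.append(
                ItemParameters(
                    slopes=slopes,
                    intercepts=self.gamma[i].copy(),
                    scoring_weights=self.weights[i].copy(),
                    item_id=iid,
                )
            )
        return items


def _item_newton_direction(
    ws: _Workspace,
    theta: np.ndarray,
    p: np.ndarray,
    ridge: float = 1e-3,
    slope_penalty: Optional[Tuple[int, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Newton direction per item for (slopes, intercepts k>=1).

    ``p`` holds current category probabilities at ``theta`` with missing cells
    zeroed.  ``slope_penalty`` = (column, lambda) adds a quadratic shrinkage
    toward 0 on one slope column (used to anneal the faking slopes during
    burn-in).  Returns (delta_alpha (I,P_s), delta_gamma (I,K)).
    """
    i_, k1, ps = ws.I, ws.K1, ws.P_s
    theta_l = theta[:, ws.load_idx]  # (N, I, P_s)
    s_t = ws.S_load.transpose(0, 2, 1)  # (I, K1, P_s)
    xs = theta_l[:, :, None, :] * s_t[None]  # (N, I, K1, P_s)
    px = p[..., None] * xs
    mean_x = px.sum(axis=2)  # (N, I, P_s)

    onehot_x = np.take_along_axis(xs, ws.Ysafe[:, :, None, None], axis=2)[:, :, 0, :]
    onehot_x = np.where(ws.obs[:, :, None], onehot_x, 0.0)
    g_a = (onehot_x - mean_x).sum(axis=0)  # (I, P_s)

    obs_counts = np.zeros((i_, k1))
    for k in range(k1):
        obs_counts[:, k] = ((ws.Ysafe == k) & ws.obs).sum(axis=0)
    p_sum = p.sum(axis=0)  # (I, K1)
    g_g = (obs_counts - p_sum)[:, 1:]  # (I, K)

    h_aa = np.einsum("nikp,nikq->ipq", px, xs, optimize=True) - np.einsum(
        "nip,niq->ipq", mean_x, mean_x, optimize=True
    )
    h_ag = px.sum(axis=0).transpose(0, 2, 1) - np.einsum(
        "nip,nik->ipk", mean_x, p, optimize=True
    )  # (I, P_s, K1)
    h_gg = np.einsum("nik,nil->ikl", p, p, optimize=True)
    h_gg *= -1.0
    diag = np.arange(k1)
    h_gg[:, diag, diag] += p_sum

    if slope_penalty is not None:
        col, lam = slope_penalty
        g_a[:, col] -= lam * ws.alpha[:, col]
        h_aa[:, col, col] += lam
    n_par = ps + (k1 - 1)
    h = np.zeros((i_, n_par, n_par))
    h[:, :ps, :ps] = h_aa
    h[:, :ps, ps:] = h_ag[:, :, 1:]
    h[:, ps:, :ps] = h_ag[:, :, 1:].transpose(0, 2, 1)
    h[:, ps:, ps:] = h_gg[:, 1:, 1:]
    h[:, np.arange(n_par), np.arange(n_par)] += ridge * (1.0 + np.abs(np.diagonal(h, axis1=1, axis2=2)))
    g = np.concatenate([g_a, g_g], axis=1)
    delta = np.linalg.solve(h, g[:, :, None])[:, :, 0]
    np.clip(delta, -1.0, 1.0, out=delta)
    return delta[:, :ps], delta[:, ps:]


# ---------------------------------------------------------------------------
# MH-RM
# ---------------------------------------------------------------------------


def _fit_mhrm(ws: _Workspace, options: FitOptions) -> Tuple[np.ndarray, bool, int, List[float]]:
    rng = np.random.default_rng(options.seed)
    n, d = ws.N, ws.D
    theta = np.zeros((n, d))
    cov = np.eye(d)
    chol = np.linalg.cholesky(cov)
    prop_sd = 0.4
    acc_rate = 0.0

    pll = ws.person_loglik(theta)
    prior = _mvn_logpdf_chol(theta, chol)
    trace: List[float] = []
    stable = 0
    converged = False
    cycle = 0
    # Staged identification of the faking dimension: during burn-in the faking
    # row of Sigma is pinned to zero (faking orthogonal to traits and ERS).
    # Under collinear scoring weights the likelihood is nearly flat along the
    # trait/faking ridge, and letting the prior lend trait variance to the
    # faking scores early on can push the chain onto a spurious
    # general-factor representation; with the orthogonality pin, the faking
    # slopes can only grow on response structure that the traits do not
    # explain.  The correlations are released after burn-in and converge
    # during the Robbins-Monro stage.
    fk = ws.spec.faking_index if ws.faking_col is not None else None

    for cycle in range(1, options.max_cycles + 1):
        burnin = cycle <= options.n_burnin
        gain = 0.5 if burnin else (cycle - options.n_burnin) ** (-options.gain_decay)

        accepted = 0
        for _ in range(options.mh_draws):
            prop = theta + prop_sd * rng.standard_normal((n, d))
            pll_prop = ws.person_loglik(prop)
            prior_prop = _mvn_logpdf_chol(prop, chol)
            log_acc = (pll_prop + prior_prop) - (pll + prior)
            take = np.log(rng.random(n)) < log_acc
            theta[take] = prop[take]
            pll[take] = pll_prop[take]
            prior[take] = prior_prop[take]
            accepted += int(take.sum())
        acc_rate = accepted / (n * options.mh_draws)
        if burnin:
            prop_sd *= math.exp(0.25 * (acc_rate - 0.3))
            prop_sd = min(max(prop_sd, 0.05), 2.5)

        p = ws.probs(theta)
        if ws._has_missing:
            p *= ws.obs[:, :, None]
        d_a, d_g = _item_newton_direction(ws, theta, p)
        d_a[ws.frozen] = 0.0
        ws.alpha += gain * d_a
        ws.gamma[:, 1:] += gain * d_g
        np.clip(ws.alpha, -8.0, 8.0, out=ws.alpha)
        np.clip(ws.gamma, -12.0, 12.0, out=ws.gamma)
        ws.invalidate()

        s_emp = theta.T @ theta / n
        cov_change = gain * (s_emp - cov)
        cov = cov + cov_change
        if fk is not None and cycle <= (2 * options.n_burnin) // 3:
            cov[fk, :] = cov[:, fk] = 0.0
            cov[fk, fk] = s_emp[fk, fk]
        sd = np.sqrt(np.diag(cov))
        ws.alpha[~ws.frozen] *= sd[ws.load_idx][~ws.frozen]
        cov = cov / np.outer(sd, sd)
        np.fill_diagonal(cov, 1.0)
        theta /= sd
        ws.invalidate()
        chol = np.linalg.cholesky(cov)
        pll = ws.person_loglik(theta)
        prior = _mvn_logpdf_chol(theta, chol)

        change = max(
            gain * float(np.max(np.abs(d_a))),
            gain * float(np.max(np.abs(d_g))),
            float(np.max(np.abs(cov_change))),
        )
        trace.append(change)
        if not burnin:
            stable = stable + 1 if change < options.tol else 0
            if stable >= options.window:
                converged = True
                break
    return cov, converged, cycle, trace


def _mvn_logpdf_chol(theta: np.ndarray, chol: np.ndarray) -> np.ndarray:
    z = solve_triangular(chol, theta.T, lower=True)
    return -0.5 * (z ** 2).sum(axis=0)


# ---------------------------------------------------------------------------
# Quadrature EM oracle
# ---------------------------------------------------------------------------


def _gh_grid(d: int, nodes: int) -> Tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/log-weights for a standard normal in d dimensions."""
    per_dim = {1: nodes, 2: nodes, 3: min(nodes, 15), 4: min(nodes, 9)}[d]
    x, w = np.polynomial.hermite_e.hermegauss(per_dim)
    logw1 = np.log(w) - 0.5 * math.log(2 * math.pi)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    z = np.stack([g.ravel() for g in grids], axis=1)
    logw = np.zeros(z.shape[0])
    for j in range(d):
        logw += np.meshgrid(*([logw1] * d), indexing="ij")[j].ravel()
    return z, logw


def _chol_from_angles(angles: np.ndarray, d: int) -> np.ndarray:
    """Unit-row lower-triangular Cholesky factor from hyperspherical angles."""
    l = np.zeros((d, d))
    l[0, 0] = 1.0
    pos = 0
    for r in range(1, d):
        phi = angles[pos : pos + r]
        pos += r
        sin_prod = 1.0
        for j in range(r):
            l[r, j] = sin_prod * math.cos(phi[j])
            sin_prod *= math.sin(phi[j])
        l[r, r] = sin_prod
    return l


def _angles_from_corr(corr: np.ndarray) -> np.ndarray:
    d = corr.shape[0]
    l = cholesky(corr + 1e-12 * np.eye(d), lower=True)
    l /= np.linalg.norm(l, axis=1, keepdims=True)
    angles = []
    for r in range(1, d):
        sin_prod = 1.0
        for j in range(r):
            c = np.clip(l[r, j] / max(sin_prod, 1e-12), -1.0, 1.0)
            phi = math.acos(c)
            angles.append(phi)
            sin_prod *= math.sin(phi)
    return np.asarray(angles)


def _node_loglik(ws: _Workspace, theta_q: np.ndarray) -> np.ndarray:
    """(Q, I, K1) log category probabilities at the quadrature nodes."""
    return ws.log_probs(theta_q)


def _em_estep(
    ws: _Workspace, lp_nodes: np.ndarray, logw: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Posterior node weights per person and the marginal log-likelihood."""
    q = lp_nodes.shape[0]
    ll_nq = np.empty((ws.N, q))
    chunk = max(1, int(2e7 // max(1, q * ws.I)))
    iidx = np.arange(ws.I)
    for start in range(0, ws.N, chunk):
        sl = slice(start, min(start + chunk, ws.N))
        cell = lp_nodes[:, iidx, ws.Ysafe[sl]]  # (Q, n_chunk, I)
        cell = np.where(ws.obs[sl][None], cell, 0.0)
        ll_nq[sl] = cell.sum(axis=2).T
    ll_nq += logw
    m = ll_nq.max(axis=1)
    post = np.exp(ll_nq - m[:, None])
    s = post.sum(axis=1)
    post /= s[:, None]
    norm = m + np.log(s)
    return float(norm.sum()), post


def _em_item_update(
    ws: _Workspace, theta_q: np.ndarray, c_counts: np.ndarray, max_newton: int = 25
) -> None:
    """Per-item Newton ascent of the expected complete-data log-likelihood.

    ``c_counts[i, q, k]`` are expected response counts per node and category;
    each item's parameters solve a node-weighted multinomial-logistic problem,
    which is concave, so Newton with step-halving cannot decrease the
    objective (and hence cannot break EM monotonicity).
    """
    k1 = ws.K1
    ident = np.zeros((k1, k1 - 1))
    ident[1:, :] = np.eye(k1 - 1)
    for i in range(ws.I):
        c = c_counts[i]  # (Q, K1)
        n_q = c.sum(axis=1)  # (Q,)
        th = theta_q[:, ws.load_idx[i]]  # (Q, P_s)
        x_slope = th[:, None, :] * ws.S_load[i].T[None]  # (Q, K1, P_s)
        free = ~ws.frozen[i]
        n_slope = int(free.sum())
        q = th.shape[0]
        # Full design: free slopes then intercept indicators (k >= 1).
        x = np.concatenate(
            [x_slope[:, :, free], np.broadcast_to(ident, (q, k1, k1 - 1))], axis=2
        )
        offset = x_slope[:, :, ~free] @ ws.alpha[i, ~free] if n_slope < ws.P_s else 0.0
        beta = np.concatenate([ws.alpha[i, free], ws.gamma[i, 1:]])

        def objective(b: np.ndarray) -> float:
            pred = x @ b + offset
            lse = logsumexp(pred, axis=1, keepdims=True)
            return float((c * (pred - lse)).sum())

        obj = objective(beta)
        for _ in range(max_newton):
            pred = x @ beta + offset
            p = np.exp(pred - logsumexp(pred, axis=1, keepdims=True))
            grad = np.einsum("qk,qkp->p", c - n_q[:, None] * p, x)
            if float(np.max(np.abs(grad))) < 1e-9 * max(1.0, float(n_q.sum())):
                break
            w = n_q[:, None] * p  # (Q, K1)
            mean_x = np.einsum("qk,qkp->qp", p, x)
            h = np.einsum("qk,qkp,qkr->pr", w, x, x) - np.einsum(
                "q,qp,qr->pr", n_q, mean_x, mean_x
            )
            npar = h.shape[0]
            h[np.arange(npar), np.arange(npar)] += 1e-8 + 1e-10 * np.abs(np.diag(h))
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                step = grad / (np.abs(np.diag(h)).max() + 1.0)
            scale, improved = 1.0, False
            for _ in range(15):
                cand = beta + scale * step
                obj_new = objective(cand)
                if obj_new >= obj - 1e-12:
                    beta, obj, improved = cand, obj_new, True
                    break
                scale *= 0.5
            if not improved:
                break
        ws.alpha[i, free] = beta[:n_slope]
        ws.gamma[i, 1:] = beta[n_slope:]
    ws.invalidate()


def _em_sigma_objective(
    ws: _Workspace, angles: np.ndarray, z: np.ndarray, c_counts: np.ndarray
) -> float:
    l = _chol_from_angles(angles, ws.D)
    theta_q = z @ l.T
    lp = _node_loglik(ws, theta_q)  # (Q, I, K1)
    return float(np.einsum("iqk,qik->", c_counts, lp, optimize=True))


def _fit_em(ws: _Workspace, options: FitOptions) -> Tuple[np.ndarray, bool, int, List[float]]:
    if ws.D > 4:
        raise ValueError("em_quadrature is limited to D <= 4")
    z, logw = _gh_grid(ws.D, options.quad_nodes)
    angles = _angles_from_corr(np.eye(ws.D)) if ws.D > 1 else np.empty(0)
    ll_prev = -np.inf
    trace: List[float] = []
    converged = False
    it = 0
    max_iter = min(options.max_cycles, 500)
    for it in range(1, max_iter + 1):
        l = _chol_from_angles(angles, ws.D) if ws.D > 1 else np.eye(1)
        theta_q = z @ l.T
        lp_nodes = _node_loglik(ws, theta_q)
        ll, post = _em_estep(ws, lp_nodes, logw)
        trace.append(ll)

        c_counts = np.zeros((ws.I, post.shape[1], ws.K1))
        for i in range(ws.I):
            for k in range(ws.K1):
                mask = (ws.Ysafe[:, i] == k) & ws.obs[:, i]
                if mask.any():
                    c_counts[i, :, k] = post[mask].sum(axis=0)

        _em_item_update(ws, theta_q, c_counts)

        if ws.D > 1 and angles.size:
            cur = _em_sigma_objective(ws, angles, z, c_counts)

            def neg(a):
                return -_em_sigma_objective(ws, a, z, c_counts)

            res = optimize.minimize(
                neg, angles, method="Nelder-Mead",
                options={"maxiter": 60 * angles.size, "xatol": 1e-5, "fatol": 1e-8},
            )
            if -res.fun > cur:
                angles = res.x

        if ll - ll_prev < 1e-7 * max(1.0, abs(ll)) and it > 2:
            converged = True
            break
        ll_prev = ll
    l = _chol_from_angles(angles, ws.D) if ws.D > 1 else np.eye(1)
    cov = l @ l.T
    np.fill_diagonal(cov, 1.0)
    return cov, converged, it, trace


# ---------------------------------------------------------------------------
# Marginal log-likelihood
# ---------------------------------------------------------------------------


def _marginal_loglik(ws: _Workspace, sigma: np.ndarray, options: FitOptions) -> float:
    """Marginal log-likelihood at the current parameters.

    Exact Gauss-Hermite quadrature for D <= 4 (node count reduced with
    dimension); for higher D a seeded antithetic Monte-Carlo estimate over
    ``loglik_mc_draws`` prior draws.
    """
    d = ws.D
    if d <= 4:
        z, logw = _gh_grid(d, options.quad_nodes)
        l = np.linalg.cholesky(sigma)
        lp_nodes = _node_loglik(ws, z @ l.T)
        ll, _ = _em_estep(ws, lp_nodes, logw)
        return ll
    rng = np.random.default_rng(0 if options.seed is None else options.seed + 7)
    m_half = max(1, options.loglik_mc_draws // 2)
    z = rng.standard_normal((m_half, d))
    z = np.concatenate([z, -z], axis=0)
    m = z.shape[0]
    l = np.linalg.cholesky(sigma)
    lp_nodes = _node_loglik(ws, z @ l.T)  # (M, I, K1)
    total = 0.0
    chunk = max(1, int(2e7 // max(1, m * ws.I)))
    iidx = np.arange(ws.I)
    for start in range(0, ws.N, chunk):
        sl = slice(start, min(start + chunk, ws.N))
        cell = lp_nodes[:, iidx, ws.Ysafe[sl]]
        cell = np.where(ws.obs[sl][None], cell, 0.0)
        ll_mn = cell.sum(axis=2)  # (M, n_chunk)
        total += float((logsumexp(ll_mn, axis=0) - math.log(m)).sum())
    return total


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def fit(
    responses: ResponseMatrix,
    spec: ModelSpec,
    weights: Union[Sequence[np.ndarray], Mapping[str, np.ndarray]],
    options: Optional[FitOptions] = None,
    frozen_slopes: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> FitResult:
    """Fit an MNRM by marginal maximum likelihood with fixed scoring weights.

    Non-convergence within the cycle budget yields a flagged result (``
    converged=False``), not an exception.  ``frozen_slopes`` maps item id ->
    {dimension label: value} for anchored slopes that are held fixed.
    """
    options = options or FitOptions()
    ws = _Workspace(responses, spec, weights, frozen_slopes)
    if options.algorithm == "em_quadrature":
        sigma, converged, cycles, trace = _fit_em(ws, options)
    else:
        sigma, converged, cycles, trace = _fit_mhrm(ws, options)
    if not converged:
        warnings.warn(
            f"fit did not converge within {cycles} cycles "
            f"(algorithm={options.algorithm})",
            RuntimeWarning,
        )
    loglik = _marginal_loglik(ws, sigma, options)
    return FitResult(
        spec=spec,
        items=ws.as_items(),
        sigma=sigma,
        loglik=loglik,
        n_params=count_free_parameters(spec, ws.n_frozen),
        n_obs=ws.N,
        converged=converged,
        n_cycles=cycles,
        algorithm=options.algorithm,
        trace=trace,
        options=options,
    )


def score_map(
    responses: ResponseMatrix,
    fit_result: FitResult,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> PersonParameters:
    """MAP latent scores under the estimated MVN(0, Sigma-hat) prior.

    The per-person posterior is strictly log-concave (multinomial-logistic
    likelihood plus normal prior), so a damped Newton iteration converges to
    the unique mode; any person not converged by ``max_iter`` is restarted
    once from a perturbed point before being flagged.
    """
    ws = _Workspace(responses, fit_result.spec, [it.scoring_weights for it in fit_result.items])
    for i, it in enumerate(fit_result.items):
        ws.alpha[i] = it.slopes[ws.load_idx[i]]
        ws.gamma[i] = it.intercepts
    ws.invalidate()
    sigma = fit_result.sigma
    prec = np.linalg.inv(sigma)
    a = ws.loading_tensor()  # (I, D, K1)

    def objective(theta: np.ndarray) -> np.ndarray:
        return ws.person_loglik(theta) - 0.5 * np.einsum(
            "nd,de,ne->n", theta, prec, theta
        )

    theta = np.zeros((ws.N, ws.D))
    obj = objective(theta)
    for _ in range(max_iter):
        p = ws.probs(theta)
        if ws._has_missing:
            p = p * ws.obs[:, :, None]
        obs_a = a[np.arange(ws.I)[None, :], :, ws.Ysafe]  # (N, I, D)
        obs_a = np.where(ws.obs[:, :, None], obs_a, 0.0)
        mean_a = np.einsum("nik,idk->nid", p, a, optimize=True)
        grad = (obs_a - mean_a).sum(axis=1) - theta @ prec
        hess = (
            np.einsum("nik,idk,iek->nde", p, a, a, optimize=True)
            - np.einsum("nid,nie->nde", mean_a, mean_a, optimize=True)
            + prec
        )
        step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
        if float(np.max(np.abs(step))) < tol:
            break
        scale = np.ones(ws.N)
        for _ in range(15):
            cand = theta + scale[:, None] * step
            obj_new = objective(cand)
            worse = obj_new < obj - 1e-12
            if not worse.any():
                theta, obj = cand, obj_new
                break
            scale[worse] *= 0.5
        else:
            better = obj_new >= obj
            theta[better] = cand[better]
            obj[better] = obj_new[better]
    return PersonParameters(values=theta)


def compare_models(fit_a: FitResult, fit_b: FitResult) -> Dict[str, float]:
    """Likelihood-ratio test and information criteria for nested fits (b over a)."""
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("models were fitted to different numbers of persons")
    labels_a = {d.label for d in fit_a.spec.dimensions}
    labels_b = {d.label for d in fit_b.spec.dimensions}
    if not labels_a <= labels_b or fit_a.spec.n_items != fit_b.spec.n_items:
        raise ValueError("fit_b must nest fit_a (same items, superset of dimensions)")
    if fit_b.n_params < fit_a.n_params:
        raise ValueError("fit_b has fewer parameters than fit_a; not nested")
    lr = 2.0 * (fit_b.loglik - fit_a.loglik)
    df = fit_b.n_params - fit_a.n_params
    if df == 0:
        p = 1.0 if abs(lr) < 1e-8 else float("nan")
    else:
        p = float(stats.chi2.sf(max(lr, 0.0), df))
    return {
        "lr_statistic": lr,
        "df": df,
        "p": p,
        "aic_a": fit_a.aic,
        "aic_b": fit_b.aic,
        "bic_a": fit_a.bic,
        "bic_b": fit_b.bic,
    }


@dataclass
class SelectionResult:
    """Outcome of anchored item selection."""

    selected: Dict[str, List[str]]
    slopes: Dict[str, float]
    fit: FitResult


def anchored_item_selection(
    responses: ResponseMatrix,
    spec: ModelSpec,
    weights: Union[Sequence[np.ndarray], Mapping[str, np.ndarray]],
    anchor_slopes: Mapping[str, Mapping[str, float]],
    m_per_trait: int,
    trajectories: Optional[Mapping[str, str]] = None,
    required_counts: Optional[Mapping[str, int]] = None,
    options: Optional[FitOptions] = None,
) -> SelectionResult:
    """Select the most discriminating candidate items with anchors frozen.

    Refits the model with the anchor items' supplied slopes held fixed, then
    ranks the remaining (candidate) items of each trait by their estimated
    trait slope and returns the top ``m_per_trait`` per trait, optionally
    constrained to given trajectory-type counts.  Ties break on item id.
    """
    result = fit(responses, spec, weights, options=options, frozen_slopes=anchor_slopes)
    est_slope = {}
    for it in result.items:
        ti = spec.dimension_index(spec.item_trait[it.item_id])
        est_slope[it.item_id] = float(it.slopes[ti])
    anchors = set(anchor_slopes)
    selected: Dict[str, List[str]] = {}
    traits = sorted({spec.item_trait[i] for i in spec.item_ids})
    for trait in traits:
        cands = [
            i for i in spec.item_ids if spec.item_trait[i] == trait and i not in anchors
        ]
        ranked = sorted(cands, key=lambda i: (-est_slope[i], i))
        if required_counts:
            if trajectories is None:
                raise ValueError("required_counts needs trajectory labels per item")
            chosen: List[str] = []
            deficits = {}
            for ttype, need in required_counts.items():
                pool = [i for i in ranked if trajectories[i] == ttype and i not in chosen]
                if len(pool) < need:
                    deficits[ttype] = need - len(pool)
                chosen.extend(pool[:need])
            if deficits:
                raise ValueError(
                    f"insufficient candidates for trait {trait}: "
                    f"missing {deficits} (trajectory type -> shortfall)"
                )
            remaining = [i for i in ranked if i not in chosen]
            chosen.extend(remaining[: max(0, m_per_trait - len(chosen))])
            selected[trait] = chosen[:m_per_trait]
        else:
            selected[trait] = ranked[:m_per_trait]
    return SelectionResult(selected=selected, slopes=est_slope, fit=result)
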