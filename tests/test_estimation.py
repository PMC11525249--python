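"""Model fitting, MAP scoring, model comparison, and anchored item selection."""

import math

import numpy as np
import pytest

from mnrm.estimate import (
    FitOptions,
    FitResult,
    anchored_item_selection,
    build_weight_matrices,
    compare_models,
    count_free_parameters,
    fit,
    score_map,
)
from mnrm.model import (
    Dimension,
    ItemParameters,
    LatentDistribution,
    ModelSpec,
    ResponseMatrix,
)
from mnrm.simulate import draw_persons, make_model_spec, sample_responses
from mnrm.weights import prototype_weights


def _make_fit_result(spec, loglik, n_params, n_obs):
    return FitResult(
        spec=spec,
        items=[],
        sigma=np.eye(spec.n_dimensions),
        loglik=loglik,
        n_params=n_params,
        n_obs=n_obs,
        converged=True,
        n_cycles=1,
        algorithm="mhrm",
    )


class TestParameterBookkeeping:
    def test_free_parameter_counts_for_thirty_item_models(self):
        traits_only = make_model_spec(6, include_ers=False, include_faking=False)
        with_ers = make_model_spec(6, include_ers=True, include_faking=False)
        with_faking = make_model_spec(6, include_ers=True, include_faking=True)
        # 30 trait slopes + 180 intercepts + 10 trait correlations.
        assert count_free_parameters(traits_only) == 220
        # Adding ERS frees 30 slopes + 5 correlations.
        assert count_free_parameters(with_ers) == 255
        assert count_free_parameters(with_ers) - count_free_parameters(traits_only) == 35
        # Adding faking frees 30 slopes + 6 correlations.
        assert count_free_parameters(with_faking) - count_free_parameters(with_ers) == 36

    def test_frozen_slopes_reduce_count(self):
        spec = make_model_spec(6, include_ers=True, include_faking=False)
        assert count_free_parameters(spec, n_frozen_slopes=4) == 251


class TestCompareModels:
    def test_identical_fits_give_zero_lr(self):
        spec = make_model_spec(6, include_ers=True, include_faking=False)
        a = _make_fit_result(spec, -100.0, 255, 500)
        out = compare_models(a, a)
        assert out["lr_statistic"] == 0.0
        assert out["df"] == 0
        assert out["p"] == 1.0

    def test_information_criteria_formulas(self):
        spec = make_model_spec(6, include_ers=False, include_faking=False)
        a = _make_fit_result(spec, -100.0, 10, 100)
        assert a.aic == pytest.approx(220.0)
        assert a.bic == pytest.approx(200.0 + 10 * math.log(100))

    def test_nested_comparison_statistics(self):
        spec_a = make_model_spec(6, include_ers=True, include_faking=False)
        spec_b = make_model_spec(6, include_ers=True, include_faking=True)
        a = _make_fit_result(spec_a, -42857.0, count_free_parameters(spec_a), 1070)
        b = _make_fit_result(spec_b, -42688.9, count_free_parameters(spec_b), 1070)
        out = compare_models(a, b)
        assert out["df"] == 36
        assert out["lr_statistic"] == pytest.approx(2 * (42857.0 - 42688.9))
        assert out["p"] < 0.001

    def test_non_nested_specs_rejected(self):
        spec_a = make_model_spec(6, include_ers=True, include_faking=False)
        spec_b = make_model_spec(6, include_ers=False, include_faking=True)
        a = _make_fit_result(spec_a, -10.0, 255, 100)
        b = _make_fit_result(spec_b, -9.0, 256, 100)
        with pytest.raises(ValueError, match="nest"):
            compare_models(a, b)

    def test_different_sample_sizes_rejected(self):
        spec = make_model_spec(6, include_ers=False, include_faking=False)
        a = _make_fit_result(spec, -10.0, 220, 100)
        b = _make_fit_result(spec, -9.0, 220, 200)
        with pytest.raises(ValueError, match="different numbers"):
            compare_models(a, b)


class TestEmOracle:
    def test_em_loglik_nondecreasing(self, gpcm_em_fit):
        trace = np.asarray(gpcm_em_fit.trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_gpcm_recovery_at_n2000(self):
        # One trait, 6 items, n=2000: slopes recovered with mean r > 0.9 and
        # small mean signed intercept error, averaged over 5 replications
        # (r over only six slope pairs is noisy in any single replication).
        rs, errs = [], []
        for seed in range(21, 26):
            rng = np.random.default_rng(seed)
            spec = ModelSpec(
                n_categories=7,
                dimensions=[Dimension("trait1", "trait")],
                item_ids=[f"i{j}" for j in range(6)],
                item_trait={f"i{j}": "trait1" for j in range(6)},
            )
            trait_w = prototype_weights("trait", 7).array[None, :]
            items = []
            for iid in spec.item_ids:
                tau = rng.normal((-1.5, -0.9, -0.3, 0.3, 0.9, 1.5), np.sqrt(0.7))
                items.append(
                    ItemParameters(
                        slopes=np.array([rng.uniform(0.25, 0.75)]),
                        intercepts=np.concatenate([[0.0], -np.cumsum(tau)]),
                        scoring_weights=trait_w,
                        item_id=iid,
                    )
                )
            latent = LatentDistribution(mean=np.zeros(1), covariance=np.eye(1))
            persons = draw_persons(2000, latent, rng)
            responses = sample_responses(persons, items, rng, item_ids=list(spec.item_ids))
            result = fit(
                responses,
                spec,
                [it.scoring_weights for it in items],
                FitOptions(algorithm="em_quadrature", seed=0),
            )
            true_slopes = np.array([it.slopes[0] for it in items])
            est_slopes = np.array([it.slopes[0] for it in result.items])
            rs.append(np.corrcoef(true_slopes, est_slopes)[0, 1])
            errs.extend(
                (est.intercepts[1:] - true.intercepts[1:]).mean()
                for est, true in zip(result.items, items)
            )
        assert np.mean(rs) > 0.9
        assert abs(np.mean(errs)) < 0.1

    def test_missing_cells_are_skipped(self, gpcm_bundle):
        from mnrm.model import MISSING, ResponseMatrix as RM

        spec, items, latent, persons, responses = gpcm_bundle
        vals = responses.values.copy()
        vals[::10, 0] = MISSING
        vals[5::17, 3] = MISSING
        holey = RM(values=vals, item_ids=list(responses.item_ids))
        result = fit(
            holey, spec, [it.scoring_weights for it in items],
            FitOptions(algorithm="em_quadrature", seed=0),
        )
        assert np.isfinite(result.loglik)
        assert result.converged
        theta = score_map(holey, result)
        assert np.all(np.isfinite(theta.values))

    def test_em_rejects_high_dimension(self, rng):
        spec = make_model_spec(6, include_ers=True, include_faking=True)
        responses = ResponseMatrix(values=rng.integers(0, 7, size=(50, 30)),
                                   item_ids=list(spec.item_ids))
        weights = build_weight_matrices(spec, trajectories=["mono_increasing"] * 30)
        with pytest.raises(ValueError, match="D <= 4"):
            fit(responses, spec, weights, FitOptions(algorithm="em_quadrature"))


class TestMapScoring:
    def test_flat_likelihood_returns_prior_mean(self, rng):
        spec = ModelSpec(
            n_categories=7,
            dimensions=[Dimension("trait1", "trait")],
            item_ids=["i0", "i1"],
            item_trait={"i0": "trait1", "i1": "trait1"},
        )
        items = [
            ItemParameters(np.zeros(1), np.zeros(7), np.zeros((1, 7)), item_id=i)
            for i in ("i0", "i1")
        ]
        result = FitResult(
            spec=spec, items=items, sigma=np.eye(1), loglik=0.0, n_params=0,
            n_obs=5, converged=True, n_cycles=1, algorithm="mhrm",
        )
        responses = ResponseMatrix(values=rng.integers(0, 7, (5, 2)),
                                   item_ids=["i0", "i1"])
        theta = score_map(responses, result)
        np.testing.assert_allclose(theta.values, 0.0, atol=1e-8)

    def test_high_weight_response_pulls_score_positive(self):
        spec = ModelSpec(
            n_categories=2,
            dimensions=[Dimension("trait1", "trait")],
            item_ids=["i0"],
            item_trait={"i0": "trait1"},
        )
        item = ItemParameters(np.array([3.0]), np.zeros(2),
                              np.array([[0.0, 1.0]]), item_id="i0")
        result = FitResult(
            spec=spec, items=[item], sigma=np.eye(1), loglik=0.0, n_params=0,
            n_obs=1, converged=True, n_cycles=1, algorithm="mhrm",
        )
        hi = score_map(ResponseMatrix(values=np.array([[1]]), item_ids=["i0"]), result)
        lo = score_map(ResponseMatrix(values=np.array([[0]]), item_ids=["i0"]), result)
        assert hi.values[0, 0] > 0 > lo.values[0, 0]

    def test_matches_grid_search_oracle(self, gpcm_em_fit, gpcm_bundle):
        from mnrm.model import category_probabilities

        _, _, _, _, responses = gpcm_bundle
        theta = score_map(responses, gpcm_em_fit)
        grid = np.linspace(-4, 4, 1601)
        for n in (0, 7, 42):
            obj = -0.5 * grid ** 2
            for i, it in enumerate(gpcm_em_fit.items):
                obj = obj + np.array(
                    [
                        np.log(category_probabilities(np.array([g]), it)[responses.values[n, i]])
                        for g in grid
                    ]
                )
            best = grid[np.argmax(obj)]
            assert theta.values[n, 0] == pytest.approx(best, abs=0.01)


class TestAnchoredSelection:
    def _selection_setup(self, rng, n=1000, slope_boost=None):
        spec = ModelSpec(
            n_categories=7,
            dimensions=[Dimension("trait1", "trait")],
            item_ids=[f"c{j}" for j in range(8)] + ["anchor"],
            item_trait={**{f"c{j}": "trait1" for j in range(8)}, "anchor": "trait1"},
        )
        trait_w = prototype_weights("trait", 7).array[None, :]
        # Three clearly discriminating candidates, five weaker ones: the
        # selection task has a well-defined answer at this sample size.
        slopes = np.concatenate(
            [rng.uniform(0.6, 0.75, size=3), rng.uniform(0.25, 0.45, size=5),
             rng.uniform(0.4, 0.6, size=1)]
        )
        order = rng.permutation(8)
        slopes = np.concatenate([slopes[:8][order], slopes[8:]])
        if slope_boost is not None:
            slopes[:] = 0.4
            slopes[slope_boost] = 0.8
        items = []
        for iid, a in zip(spec.item_ids, slopes):
            tau = rng.normal((-1.5, -0.9, -0.3, 0.3, 0.9, 1.5), np.sqrt(0.7))
            items.append(
                ItemParameters(np.array([a]), np.concatenate([[0.0], -np.cumsum(tau)]),
                               trait_w, item_id=iid)
            )
        latent = LatentDistribution(mean=np.zeros(1), covariance=np.eye(1))
        persons = draw_persons(n, latent, rng)
        responses = sample_responses(persons, items, rng, item_ids=list(spec.item_ids))
        weights = [it.scoring_weights for it in items]
        return spec, items, responses, weights, slopes

    def test_double_slope_candidate_selected_first_and_anchor_frozen(self):
        rng = np.random.default_rng(3)
        spec, items, responses, weights, slopes = self._selection_setup(
            rng, slope_boost=2
        )
        sel = anchored_item_selection(
            responses, spec, weights,
            anchor_slopes={"anchor": {"trait1": 0.55}},
            m_per_trait=1,
            options=FitOptions(algorithm="em_quadrature", seed=0),
        )
        assert sel.selected["trait1"] == ["c2"]
        anchor_fit = [it for it in sel.fit.items if it.item_id == "anchor"][0]
        assert anchor_fit.slopes[0] == pytest.approx(0.55, abs=1e-12)

    def test_selection_matches_true_ranking_in_most_replicates(self):
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            spec, items, responses, weights, slopes = self._selection_setup(rng)
            sel = anchored_item_selection(
                responses, spec, weights,
                anchor_slopes={"anchor": {"trait1": float(slopes[-1])}},
                m_per_trait=3,
                options=FitOptions(algorithm="em_quadrature", seed=0),
            )
            true_top = set(
                np.array(spec.item_ids[:8])[np.argsort(-slopes[:8], kind="stable")][:3]
            )
            if set(sel.selected["trait1"]) == true_top:
                hits += 1
        assert hits >= 0.9 * n_reps

    def test_insufficient_trajectory_candidates_reported(self):
        rng = np.random.default_rng(5)
        spec, items, responses, weights, _ = self._selection_setup(rng, n=200)
        trajectories = {i: "mono_increasing" for i in spec.item_ids}
        with pytest.raises(ValueError, match="insufficient .*inverted_u"):
            anchored_item_selection(
                responses, spec, weights,
                anchor_slopes={"anchor": {"trait1": 0.5}},
                m_per_trait=2,
                trajectories=trajectories,
                required_counts={"inverted_u": 2},
                options=FitOptions(algorithm="em_quadrature", seed=0, max_cycles=5),
            )
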