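"""Design enumeration, trajectory compositions, and generating distributions."""

import numpy as np
import pytest
from scipy import stats

from mnrm.model import ItemParameters, PersonParameters
from mnrm.simulate import (
    FAKING_TRAIT_CORRELATIONS,
    SimulationCondition,
    TRAIT_PAIR_CORRELATIONS,
    build_composition,
    draw_item_parameters,
    draw_persons,
    draw_trait_pair_sigma,
    enumerate_design,
    make_model_spec,
    sample_responses,
    simulate_dataset,
)
from mnrm.weights import TRAJECTORY_ORDER


class TestDesignEnumeration:
    def test_full_factorial_yields_180_conditions(self):
        assert len(enumerate_design()) == 180

    def test_restricting_sample_size_factor(self):
        assert len(enumerate_design(sample_sizes=[1000])) == 60

    def test_replication_expansion(self):
        assert len(enumerate_design(replications=10)) == 1800
        labels = {c.label() for c in enumerate_design(replications=10)}
        assert len(labels) == 1800

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            SimulationCondition(9, 6, 500, True, "high")
        with pytest.raises(ValueError):
            SimulationCondition(1, 6, 500, True, "extreme")


class TestCompositions:
    @pytest.mark.parametrize(
        "items, comp, expected",
        [
            (6, 1, {"mono_increasing": 6}),
            (6, 2, {"mono_increasing": 3, "nonmono_increasing": 3}),
            (6, 3, {"mono_increasing": 2, "nonmono_increasing": 2, "inverted_u": 2}),
            (12, 4, {t: 3 for t in TRAJECTORY_ORDER[:4]}),
            (6, 4, {"mono_increasing": 2, "nonmono_increasing": 1,
                    "inverted_u": 1, "nonmono_decreasing": 2}),
            (12, 5, {"mono_increasing": 3, "nonmono_increasing": 2, "inverted_u": 2,
                     "nonmono_decreasing": 2, "mono_decreasing": 3}),
        ],
    )
    def test_known_compositions(self, items, comp, expected):
        labels = build_composition(items, comp)
        counts = {t: labels.count(t) for t in set(labels)}
        assert counts == expected

    def test_composition5_six_items_alternates_by_trait(self):
        c0 = build_composition(6, 5, trait_index=0)
        c1 = build_composition(6, 5, trait_index=1)
        assert sorted(c0) != sorted([]) and len(c0) == len(c1) == 6
        counts0 = [c0.count(t) for t in TRAJECTORY_ORDER]
        counts1 = [c1.count(t) for t in TRAJECTORY_ORDER]
        assert counts0 == [2, 1, 1, 1, 1]
        assert counts1 == [1, 1, 1, 1, 2]
        # Alternation keeps the monotone endpoints balanced across traits.
        assert counts0 == counts1[::-1]

    def test_counts_always_sum_to_items_per_trait(self):
        for comp in range(1, 6):
            for items in (6, 12):
                assert len(build_composition(items, comp)) == items

    def test_counts_within_one_item_of_exact_proportions(self):
        from mnrm.simulate import COMPOSITION_PROPORTIONS

        for comp in range(1, 6):
            for items in (6, 12):
                for ti in range(5):
                    labels = build_composition(items, comp, trait_index=ti)
                    for t in TRAJECTORY_ORDER:
                        exact = COMPOSITION_PROPORTIONS[comp].get(t, 0.0) * items
                        assert abs(labels.count(t) - exact) <= 1.0

    def test_invalid_composition_id(self):
        with pytest.raises(ValueError):
            build_composition(6, 0)


class TestItemParameterGeneration:
    def _draw_many(self, impact, ers, n_reps=40):
        spec = make_model_spec(12)
        items = []
        for rep in range(n_reps):
            cond = SimulationCondition(3, 12, 500, ers, impact, replication=rep)
            rng = np.random.default_rng(rep)
            drawn, _ = draw_item_parameters(cond, spec, rng)
            items.extend(drawn)
        return spec, items

    def test_intercepts_from_mean_thresholds(self):
        # tau = (-1.5,-0.9,-0.3,0.3,0.9,1.5) gives gamma = (0,1.5,2.4,2.7,2.4,1.5,0).
        from mnrm.simulate import _intercepts_from_thresholds

        gamma = _intercepts_from_thresholds(np.array([-1.5, -0.9, -0.3, 0.3, 0.9, 1.5]))
        np.testing.assert_allclose(gamma, [0, 1.5, 2.4, 2.7, 2.4, 1.5, 0], atol=1e-12)

    def test_trait_slope_distribution(self):
        spec, items = self._draw_many("high", True)
        trait_slopes = np.array(
            [it.slopes[spec.dimension_index(spec.item_trait[it.item_id])] for it in items]
        )
        assert trait_slopes.min() >= 0.25 and trait_slopes.max() <= 0.75
        assert trait_slopes.mean() == pytest.approx(0.5, abs=0.01)

    def test_faking_slopes_by_impact(self):
        spec, items_none = self._draw_many("none", True, n_reps=5)
        fi = spec.faking_index
        assert all(it.slopes[fi] == 0.0 for it in items_none)
        _, items_low = self._draw_many("low", True, n_reps=40)
        low = np.array([it.slopes[fi] for it in items_low])
        assert low.min() >= 0.0 and low.max() <= 0.5
        assert low.mean() == pytest.approx(0.25, abs=0.01)
        _, items_high = self._draw_many("high", True, n_reps=40)
        high = np.array([it.slopes[fi] for it in items_high])
        assert high.min() >= 0.25 and high.max() <= 0.75

    def test_ers_slopes_absent_when_not_modeled(self):
        spec, items = self._draw_many("high", False, n_reps=5)
        assert all(it.slopes[spec.ers_index] == 0.0 for it in items)

    def test_first_intercept_always_zero(self):
        spec, items = self._draw_many("high", True, n_reps=5)
        assert all(it.intercepts[0] == 0.0 for it in items)


class TestPersonGeneration:
    def test_single_person_shape(self, rng):
        latent, _ = draw_trait_pair_sigma(rng)
        p = draw_persons(1, latent, rng)
        assert p.values.shape == (1, 7)

    def test_printed_correlation_matrix_is_positive_definite(self):
        # Identity assignment of the meta-analytic values to the trait pairs.
        sigma = np.eye(7)
        iu = np.triu_indices(5, k=1)
        sigma[:5, :5][iu] = TRAIT_PAIR_CORRELATIONS
        sigma[:5, :5][(iu[1], iu[0])] = TRAIT_PAIR_CORRELATIONS
        sigma[6, :5] = sigma[:5, 6] = FAKING_TRAIT_CORRELATIONS
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_permuted_sigma_keeps_value_multiset_and_pd(self, rng):
        latent, perm = draw_trait_pair_sigma(rng)
        assert sorted(perm) == list(range(10))
        iu = np.triu_indices(5, k=1)
        observed = sorted(latent.covariance[:5, :5][iu])
        assert observed == sorted(TRAIT_PAIR_CORRELATIONS)
        latent.assert_positive_definite()
        np.testing.assert_allclose(latent.covariance[5, :5], 0.0)  # ERS orthogonal
        np.testing.assert_allclose(latent.covariance[6, :5], FAKING_TRAIT_CORRELATIONS)

    def test_faking_trait_correlations_recovered_in_large_sample(self, rng):
        latent, _ = draw_trait_pair_sigma(rng)
        persons = draw_persons(100_000, latent, rng)
        emp = np.corrcoef(persons.values, rowvar=False)
        np.testing.assert_allclose(emp[6, :5], FAKING_TRAIT_CORRELATIONS, atol=0.01)


class TestResponseSampling:
    def test_uniform_limit_frequencies(self, rng):
        items = [
            ItemParameters(np.zeros(1), np.zeros(7), np.zeros((1, 7)), item_id=f"i{j}")
            for j in range(10)
        ]
        persons = PersonParameters(values=rng.normal(0, 1, (10_000, 1)))
        resp = sample_responses(persons, items, rng)
        counts = np.bincount(resp.values.ravel(), minlength=7)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_degenerate_slope_forces_top_category(self, rng):
        item = ItemParameters(
            np.array([50.0]), np.zeros(7), np.arange(7.0)[None], item_id="i1"
        )
        persons = PersonParameters(values=np.full((500, 1), 3.0))
        resp = sample_responses(persons, [item], rng)
        assert (resp.values == 6).mean() > 0.999

    def test_cell_frequencies_match_analytic_probabilities(self, rng):
        from mnrm.model import category_probabilities

        item = ItemParameters(
            np.array([0.6]),
            np.concatenate([[0.0], rng.normal(0, 1, 6)]),
            np.arange(7.0)[None],
            item_id="i1",
        )
        theta = np.array([0.7])
        persons = PersonParameters(values=np.tile(theta, (20_000, 1)))
        resp = sample_responses(persons, [item], rng)
        emp = np.bincount(resp.values[:, 0], minlength=7) / 20_000
        p = category_probabilities(theta, item)
        se = np.sqrt(p * (1 - p) / 20_000)
        assert np.all(np.abs(emp - p) < 5 * se + 1e-4)

    def test_marginal_frequencies_match_quadrature_mixture(self, rng):
        # Over theta ~ N(0,1) the observed category frequencies converge to
        # the quadrature integral of p(k | theta).
        from mnrm.model import category_probabilities

        item = ItemParameters(
            np.array([0.5]),
            np.array([0.0, 1.5, 2.4, 2.7, 2.4, 1.5, 0.0]),
            np.arange(7.0)[None],
            item_id="i1",
        )
        nodes, wts = np.polynomial.hermite_e.hermegauss(41)
        wts = wts / np.sqrt(2 * np.pi)
        mix = sum(
            w * category_probabilities(np.array([x]), item) for x, w in zip(nodes, wts)
        )
        persons = PersonParameters(values=rng.normal(0, 1, (40_000, 1)))
        resp = sample_responses(persons, [item], rng)
        emp = np.bincount(resp.values[:, 0], minlength=7) / 40_000
        np.testing.assert_allclose(emp, mix, atol=0.01)


class TestEndToEnd:
    def test_identical_seeds_give_bit_identical_datasets(self):
        cond = SimulationCondition(2, 6, 120, True, "low", replication=4)
        r1, m1 = simulate_dataset(cond, master_seed=9)
        r2, m2 = simulate_dataset(cond, master_seed=9)
        np.testing.assert_array_equal(r1.values, r2.values)
        np.testing.assert_array_equal(m1.persons.values, m2.persons.values)
        assert m1.trajectories == m2.trajectories
        assert m1.trait_pair_permutation == m2.trait_pair_permutation

    def test_different_replications_differ(self):
        c4 = SimulationCondition(2, 6, 120, True, "low", replication=4)
        c5 = SimulationCondition(2, 6, 120, True, "low", replication=5)
        r1, _ = simulate_dataset(c4, master_seed=9)
        r2, _ = simulate_dataset(c5, master_seed=9)
        assert not np.array_equal(r1.values, r2.values)

    def test_manifest_consistency(self):
        cond = SimulationCondition(3, 6, 80, False, "none", replication=0)
        resp, truth = simulate_dataset(cond, master_seed=2)
        assert resp.values.shape == (80, 30)
        assert len(truth.trajectories) == 30
        assert truth.latent.covariance.shape == (7, 7)
        fi = truth.spec.faking_index
        assert all(it.slopes[fi] == 0 for it in truth.items)
        per_trait = {}
        for iid, traj in zip(truth.spec.item_ids, truth.trajectories):
            per_trait.setdefault(truth.spec.item_trait[iid], []).append(traj)
        for labels in per_trait.values():
            assert sorted(labels) == sorted(build_composition(6, 3))
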