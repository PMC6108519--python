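"""Synthetic cohort generator: precision construction, copula margins,
reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mealnets.foods import FOOD_GROUPS, OCCASIONS, REFERENCE_MEAL_INTAKE
from mealnets.synthetic import (
    CohortSpec,
    GraphSpec,
    InfeasibleGraphError,
    MarginSpec,
    generate_recalls,
    latent_correlation,
    make_precision,
    potsdam_preset,
    simulate_cohort,
)
from conftest import single_meal_cohort


def realized_pcors(omega, edges):
    d = np.sqrt(np.diag(omega))
    return [-omega[i, j] / (d[i] * d[j]) for i, j, _ in edges]


class TestMakePrecision:
    def test_empty_graph_gives_identity(self):
        omega = make_precision(GraphSpec.empty(6))
        assert np.array_equal(omega, np.eye(6))

    def test_hub_five_nodes_hits_target(self):
        spec = GraphSpec.hub(5, 0.3)
        assert [(i, j) for i, j, _ in spec.edges] == [(0, 1), (0, 2), (0, 3), (0, 4)]
        omega = make_precision(spec)
        off = omega[~np.eye(5, dtype=bool)]
        assert int((off != 0).sum()) == 8  # 4 symmetric pairs
        # numeric check through the inverse: the implied covariance must be
        # SPD and reproduce the requested partial correlations
        sigma = np.linalg.inv(omega)
        assert np.linalg.eigvalsh(sigma)[0] > 0
        for pc in realized_pcors(omega, spec.edges):
            assert 0.25 <= pc <= 0.35

    def test_negative_sign_edges(self):
        spec = GraphSpec(3, "custom", ((0, 1, -1), (1, 2, 1)), 0.4)
        pcs = realized_pcors(make_precision(spec), spec.edges)
        assert pcs[0] < 0 < pcs[1]
        assert abs(abs(pcs[0]) - 0.4) < 0.05

    def test_infeasible_chain_errors_or_stays_pd(self):
        try:
            omega = make_precision(GraphSpec.chain(3, 0.9))
        except InfeasibleGraphError as err:
            assert "0.9" in str(err)
        else:
            assert np.linalg.eigvalsh(omega)[0] > 0

    def test_validation(self):
        with pytest.raises(ValueError):
            GraphSpec(3, "custom", ((0, 0, 1),), 0.3)  # self edge
        with pytest.raises(ValueError):
            GraphSpec(3, "custom", ((1, 0, 1),), 0.3)  # not i < j
        with pytest.raises(ValueError):
            GraphSpec(3, "custom", (), 1.2)  # pcor out of range


class TestMarginSpec:
    def test_moment_matching_without_zero_mass(self):
        # when the dispersion fits a lognormal alone, mean and SD match exactly
        spec = MarginSpec.from_moments([52.09], [33.41])
        assert spec.zero_probability[0] == 0.0
        meanlog, sdlog = spec.params[0]
        m1 = np.exp(meanlog + sdlog**2 / 2)
        sd = m1 * np.sqrt(np.exp(sdlog**2) - 1.0)
        assert m1 == pytest.approx(52.09, rel=1e-9)
        assert sd == pytest.approx(33.41, rel=1e-9)

    def test_heavy_zero_mass_for_sparse_groups(self):
        spec = MarginSpec.from_moments([0.01, 0.0], [0.40, 0.0])
        assert all(0.9 < z < 1.0 for z in spec.zero_probability)

    def test_rejects_zero_probability_one(self):
        with pytest.raises(ValueError):
            MarginSpec(zero_probability=(1.0,), params=((0.0, 1.0),))


class TestGenerateRecalls:
    def test_no_zero_inflation_gives_no_zeros_and_null_correlations(self):
        ds, groups = single_meal_cohort(GraphSpec.empty(5), n_obs=500,
                                        zero_probability=0.0, seed=11)
        meal = ds.records[ds.records.occasion == "lunch"]
        # every (day, group) cell present and positive
        assert len(meal) == 500 * 5
        assert (meal.grams > 0).all()
        wide = meal.pivot_table(index=["participant_id", "recall_index"],
                                columns="food_group", values="grams").to_numpy()
        rho = stats.spearmanr(wide).statistic
        off = rho[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.12

    def test_zero_fraction_matches_zero_probability(self):
        ds, groups = single_meal_cohort(GraphSpec.empty(4), n_obs=1500,
                                        zero_probability=0.9, seed=12)
        meal = ds.records[ds.records.occasion == "lunch"]
        for g in groups:
            frac_zero = 1.0 - (meal.food_group == g).sum() / 1500
            assert 0.85 <= frac_zero <= 0.95

    def test_recall_day_counting_with_three_recalls_each(self):
        cohort, margins = potsdam_preset(seed=5)
        cohort = dataclasses.replace(cohort, recalls_per_participant={3: 1.0})
        ds = generate_recalls(cohort, margins)
        assert ds.n_recall_days == 814 * 3 == 2442
        for meal in cohort.main_meals:
            n_obs = ds.records[ds.records.occasion == meal][
                ["participant_id", "recall_index"]].drop_duplicates().shape[0]
            assert n_obs <= 2442

    def test_copula_preserved_under_monotone_margins(self):
        # Spearman of the observed amounts matches the latent Gaussian
        # population value (6/pi) asin(rho/2) when there is no zero mass
        graph = GraphSpec.chain(4, 0.4, seed=3)
        ds, groups = single_meal_cohort(graph, n_obs=5000,
                                        zero_probability=0.0, seed=13)
        meal = ds.records[ds.records.occasion == "lunch"]
        wide = meal.pivot_table(index=["participant_id", "recall_index"],
                                columns="food_group", values="grams",
                                fill_value=0.0)[list(groups)].to_numpy()
        rho_obs = stats.spearmanr(wide).statistic
        corr = latent_correlation(graph)
        rho_pop = (6.0 / np.pi) * np.arcsin(corr / 2.0)
        for i, j, _ in graph.edges:
            assert abs(rho_obs[i, j] - rho_pop[i, j]) < 0.05

    def test_zero_inflation_never_flips_spearman_sign(self):
        graph = GraphSpec(2, "custom", ((0, 1, 1),), 0.4)
        neg = GraphSpec(2, "custom", ((0, 1, -1),), 0.4)
        for spec, expected_sign in ((graph, 1), (neg, -1)):
            ds, groups = single_meal_cohort(spec, n_obs=10000,
                                            zero_probability=0.5, seed=14)
            meal = ds.records[ds.records.occasion == "lunch"]
            # reconstruct the full day grid: days with nothing consumed are
            # implicit zeros and must enter the population Spearman
            full = np.zeros((10000, 2))
            for col, g in enumerate(groups):
                sub = meal[meal.food_group == g]
                full[sub.participant_id.to_numpy() - 1, col] = sub.grams.to_numpy()
            rho = stats.spearmanr(full[:, 0], full[:, 1]).statistic
            assert np.sign(rho) == expected_sign
            # attenuation is one-sided: magnitude shrinks, sign survives
            assert abs(rho) < 0.4

    def test_identical_seed_reproduces_byte_identical_csv(self, tmp_path):
        a = simulate_cohort(seed=21, n_participants=25)
        b = simulate_cohort(seed=21, n_participants=25)
        assert a.records.equals(b.records)
        a.to_csv(tmp_path / "a.csv")
        b.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestPotsdamPreset:
    def test_shape_of_the_preset(self):
        cohort, margins = potsdam_preset()
        assert cohort.n_participants == 814
        assert len(cohort.occasion_labels) == 11
        assert len(cohort.food_groups) == 39
        assert set(cohort.food_groups) == set(REFERENCE_MEAL_INTAKE)
        assert set(cohort.meal_graphs) == set(cohort.main_meals)
        assert len(cohort.main_meals) == 4
        assert set(margins) == set(cohort.main_meals)

    def test_breakfast_bread_mean_matches_reference(self):
        ds = simulate_cohort(seed=31)
        breakfast = ds.records[ds.records.occasion == "breakfast"]
        n_days = ds.n_recall_days
        bread_mean = breakfast[breakfast.food_group == "Bread"].grams.sum() / n_days
        assert bread_mean == pytest.approx(52.09, rel=0.15)

    def test_meal_graphs_differ_by_meal(self):
        cohort, _ = potsdam_preset()
        edge_sets = {m: frozenset((i, j) for i, j, _ in g.edges)
                     for m, g in cohort.meal_graphs.items()}
        assert len(set(edge_sets.values())) == 4

    def test_specs_round_trip_through_yaml(self, tmp_path):
        from mealnets.synthetic import load_specs, save_specs

        cohort, margins = potsdam_preset(seed=4)
        save_specs(tmp_path / "specs.yaml", cohort, margins)
        cohort2, margins2 = load_specs(tmp_path / "specs.yaml")
        assert cohort2 == cohort
        assert margins2 == margins
        a = generate_recalls(cohort, margins)
        b = generate_recalls(cohort2, margins2)
        assert a.records.equals(b.records)

    def test_cohort_validation_guards(self):
        cohort, _ = potsdam_preset()
        with pytest.raises(ValueError):
            dataclasses.replace(cohort, occasion_labels=OCCASIONS[:10])
        with pytest.raises(ValueError):
            dataclasses.replace(cohort, recalls_per_participant={1: 0.5, 2: 0.2})
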