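"""The three diet-specialization generators and the environment generator."""

import numpy as np
import pytest

from indivnet import (
    DietModelParams,
    EnvironmentDesign,
    generate_study,
    matrix_temperature,
    monte_carlo_test,
    metric_evaluator,
    shannon_exp_diversity,
    simulate_competitive_refuge,
    simulate_distinct_preference,
    simulate_environment,
    simulate_shared_preference,
)


def mean_jaccard(values: np.ndarray) -> float:
    rows = values.astype(bool)
    n = len(rows)
    overlaps = []
    for i in range(n):
        for j in range(i + 1, n):
            union = (rows[i] | rows[j]).sum()
            if union:
                overlaps.append((rows[i] & rows[j]).sum() / union)
    return float(np.mean(overlaps))


class TestSharedPreference:
    def test_distinct_breadths_give_perfect_staircase(self):
        params = DietModelParams(
            model="shared_preference", n_individuals=8, n_resources=8, noise=0.0, seed=1
        )
        m = simulate_shared_preference(params, breadths=range(1, 9))
        assert matrix_temperature(m, effort="fast").temperature == 0.0

    def test_equal_breadths_give_identical_rows(self):
        params = DietModelParams(
            model="shared_preference", n_individuals=6, n_resources=10,
            breadth_distribution=(4, 4), noise=0.0, seed=2,
        )
        m = simulate_shared_preference(params)
        assert (m.values == m.values[0]).all()

    def test_noise_free_matrices_always_perfectly_nested(self):
        for seed in range(10):
            params = DietModelParams(
                model="shared_preference", n_individuals=15, n_resources=12,
                breadth_distribution=(1, 12), noise=0.0, seed=seed,
            )
            m = simulate_shared_preference(params)
            assert matrix_temperature(m, seed=seed, effort="fast").temperature == 0.0

    def test_nestedness_ses_exceeds_two_in_most_seeds(self):
        # the generator's nested structure is detected against the ER null
        effort = {"restarts": 1, "iters_per_node": 10}
        fn = metric_evaluator("nestedness", effort=effort)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            params = DietModelParams(
                model="shared_preference", n_individuals=20, n_resources=15,
                breadth_distribution=(1, 15), noise=0.0, seed=seed,
            )
            m = simulate_shared_preference(params)
            result = monte_carlo_test(fn(m), fn, m, n_sim=30, seed=seed)
            if result.ses > 2:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestDistinctPreference:
    def test_zero_density_gives_single_item_diets(self):
        params = DietModelParams(
            model="distinct_preference", n_individuals=12, n_resources=10,
            density=0.0, breadth_distribution=(1, 10), noise=0.0, seed=3,
        )
        m = simulate_distinct_preference(params)
        # pruning drops unconsumed resources; every row keeps exactly one item
        assert (m.values.sum(axis=1) == 1).all()

    def test_full_density_gives_all_ones(self):
        params = DietModelParams(
            model="distinct_preference", n_individuals=6, n_resources=8,
            density=1.0, breadth_distribution=(1, 8), noise=0.0, seed=4,
        )
        m = simulate_distinct_preference(params)
        assert m.values.all()

    def test_diet_overlap_increases_with_density(self):
        overlaps = {}
        for density in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(50):
                params = DietModelParams(
                    model="distinct_preference", n_individuals=15, n_resources=12,
                    density=density, breadth_distribution=(1, 12), noise=0.0, seed=seed,
                )
                vals.append(mean_jaccard(simulate_distinct_preference(params).values))
            overlaps[density] = float(np.mean(vals))
        assert overlaps[0.0] < overlaps[0.5] < overlaps[1.0]


class TestCompetitiveRefuge:
    def test_zero_density_leaves_only_the_shared_core(self):
        params = DietModelParams(
            model="competitive_refuge", n_individuals=10, n_resources=15,
            density=0.0, core_size=4, n_groups=3, noise=0.0, seed=5,
        )
        m = simulate_competitive_refuge(params)
        assert m.shape == (10, 4)
        assert m.values.all()

    def test_full_density_gives_block_structure(self):
        params = DietModelParams(
            model="competitive_refuge", n_individuals=12, n_resources=14,
            density=1.0, core_size=4, n_groups=2, noise=0.0, seed=6,
        )
        m = simulate_competitive_refuge(params)
        values = np.asarray(m.values)
        assert values[:, :4].all()  # core columns saturated
        alt = values[:, 4:]
        # each alternative column is used by exactly one of the two groups
        patterns = {tuple(alt[:, j]) for j in range(alt.shape[1])}
        assert len(patterns) == 2
        a, b = (np.array(p, dtype=bool) for p in patterns)
        assert not (a & b).any() and (a | b).all()

    def test_too_many_groups_is_error(self):
        with pytest.raises(ValueError, match="n_groups"):
            simulate_competitive_refuge(
                DietModelParams(
                    model="competitive_refuge", n_resources=10, core_size=8, n_groups=5
                )
            )


class TestModelDiscrimination:
    def test_generators_carry_their_network_signatures(self):
        # shared preference is the more nested construction, competitive
        # refuge the more modular one, relative to the ER null
        effort = {"restarts": 1, "iters_per_node": 10}
        fn_nest = metric_evaluator("nestedness", effort=effort)
        fn_mod = metric_evaluator("modularity")
        ses = {m: {"nest": [], "mod": []} for m in ("shared", "refuge")}
        for seed in range(6):
            shared = simulate_shared_preference(
                DietModelParams(
                    model="shared_preference", n_individuals=20, n_resources=15,
                    breadth_distribution=(1, 15), noise=0.05, seed=seed,
                )
            )
            refuge = simulate_competitive_refuge(
                DietModelParams(
                    model="competitive_refuge", n_individuals=20, n_resources=15,
                    core_size=4, n_groups=3, density=0.55, noise=0.05, seed=seed,
                )
            )
            for name, m in (("shared", shared), ("refuge", refuge)):
                ses[name]["nest"].append(
                    monte_carlo_test(fn_nest(m), fn_nest, m, n_sim=30, seed=seed).ses
                )
                ses[name]["mod"].append(
                    monte_carlo_test(fn_mod(m), fn_mod, m, n_sim=100, seed=seed).ses
                )
        assert np.mean(ses["shared"]["nest"]) > np.mean(ses["refuge"]["nest"])
        assert np.mean(ses["refuge"]["mod"]) > np.mean(ses["shared"]["mod"])


class TestEnvironmentGenerator:
    def test_warm_wet_is_more_diverse_in_most_seeds(self):
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            resources, _ = simulate_environment(seed=seed)
            mass_cols = [c for c in resources.columns if c.startswith("mass_")]
            div = resources.apply(
                lambda r: shannon_exp_diversity({c: r[c] for c in mass_cols}), axis=1
            )
            resources = resources.assign(div=div)
            means = resources.groupby("season")["div"].mean()
            if means["warm_wet"] > means["cool_dry"]:
                wins += 1
        assert wins >= 0.9 * n_seeds

    def test_zero_season_effect_balances_the_seasons(self):
        design = EnvironmentDesign(
            arthropod_sigma={"cool_dry": 1.0, "warm_wet": 1.0},
            arthropod_mean_mass={"cool_dry": 1.0, "warm_wet": 1.0},
            fruit_mean={"cool_dry": 300.0, "warm_wet": 300.0},
            season_factor_shift={"cool_dry": 0.0, "warm_wet": 0.0},
        )
        fruit_diff = []
        for seed in range(40):
            resources, _ = simulate_environment(design, seed=seed)
            means = resources.groupby("season")["fruit_count"].mean()
            fruit_diff.append(means["warm_wet"] - means["cool_dry"])
        # no systematic seasonal difference beyond Monte-Carlo error
        se = np.std(fruit_diff, ddof=1) / np.sqrt(len(fruit_diff))
        assert abs(np.mean(fruit_diff)) < 3 * se + 1e-9

    def test_same_seed_reproduces_the_study(self):
        a = generate_study(seed=11)
        b = generate_study(seed=11)
        assert a.manifest == b.manifest
        assert a.resources.equals(b.resources)
        assert a.habitat.equals(b.habitat)
        for key in a.matrices:
            assert a.matrices[key] == b.matrices[key]

    def test_station_counts_in_design_range(self):
        _, habitat = simulate_environment(seed=0)
        counts = habitat.groupby(["site", "season"]).size()
        assert counts.between(57, 78).all()
        assert len(counts) == 8
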