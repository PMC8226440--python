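import itertools

import numpy as np
import pytest

from matekit import (
    STRATEGY_NAMES,
    InfeasibleError,
    KinshipMatrix,
    MatingPlan,
    StrategySpec,
    all_strategies,
    feasible,
    objective_value,
    offspring_kinship,
    optimize_plan,
    parse_strategy,
    random_mating_pedigree,
    random_plan,
)
from matekit.strategies import check_feasible, enumeration_size


def instance(seed, nm=3, nf=4, depth=4):
    """Random candidate group with a structurally valid kinship matrix."""
    ids = [f"M{i}" for i in range(nm)] + [f"F{i}" for i in range(nf)]
    ped, cohort = random_mating_pedigree(
        8, depth, seed=seed, cohort_size=nm + nf
    )
    K = ped.kinship(cohort).values
    eg = {i: float(depth) for i in ids}
    return KinshipMatrix(tuple(ids), K), eg, ids[:nm], ids[nm:]


class TestStrategyRegistry:
    def test_exactly_23_strategies(self):
        assert len(STRATEGY_NAMES) == 23
        assert len(set(STRATEGY_NAMES)) == 23

    def test_printed_names_resolve(self):
        assert parse_strategy("ΔF0").name == "dF0"
        assert parse_strategy("mixf 5-95").name == "mixf5-95"
        assert parse_strategy("Ff").participation == "free"
        assert parse_strategy("mix95-5").p1 == 0.95
        assert parse_strategy("mix1-99").participation == "zero"

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(KeyError, match="mixf5-95"):
            parse_strategy("bogus")

    def test_p1_required_iff_mix(self):
        with pytest.raises(ValueError):
            StrategySpec("mix", "free")
        with pytest.raises(ValueError):
            StrategySpec("F", "zero", p1=0.5)
        with pytest.raises(ValueError):
            StrategySpec("dF", "free")  # dF has no free variant


class TestOffspringKinship:
    def test_unrelated_founder_parents(self, founder_group):
        kin = founder_group.kinship()
        plan = MatingPlan((("M1", "F1"), ("M2", "F2")))
        off = offspring_kinship(plan, kin)
        assert off.values[0, 1] == 0.0
        assert off.values[0, 0] == 0.5

    def test_paternal_half_sibs(self, founder_group):
        kin = founder_group.kinship()
        plan = MatingPlan((("M1", "F1"), ("M1", "F2")))
        off = offspring_kinship(plan, kin)
        # shared sire: C_lm = C_AA / 4 = 0.125
        assert off.values[0, 1] == pytest.approx(0.125)

    def test_matches_pedigree_extension(self):
        """The one-generation recursion must agree with appending the
        offspring to the pedigree and recomputing kinship."""
        from matekit import FEMALE, MALE, Individual, Pedigree

        ped, cohort = random_mating_pedigree(8, 3, seed=5, cohort_size=6)
        kin = ped.kinship(cohort)
        males = [i for i in cohort if ped[i].sex == MALE][:2]
        females = [i for i in cohort if ped[i].sex == FEMALE][:2]
        plan = MatingPlan((
            (males[0], females[0]), (males[0], females[1]), (males[1], females[1]),
        ))
        off = offspring_kinship(plan, kin)
        inds = list(ped)
        for k, (s, d) in enumerate(plan.pairs):
            inds.append(Individual(f"new{k}", s, d, MALE, birth_time=99.0))
        extended = Pedigree(inds).kinship([f"new{k}" for k in range(3)])
        assert np.allclose(off.values, extended.values, atol=1e-12)


class TestObjectiveValue:
    def test_founder_parents_all_strategies_zero(self, founder_group):
        kin = founder_group.kinship()
        eg = {i: 2.0 for i in kin.ids}
        plan = MatingPlan((("M1", "F1"), ("M2", "F2")))
        for spec in all_strategies():
            assert objective_value(plan, spec, kin, eg=eg) == pytest.approx(0.0)

    def test_family_f_is_direct_sum(self):
        ids = ("M1", "M2", "F1", "F2")
        K = np.full((4, 4), 0.0)
        np.fill_diagonal(K, 0.5)
        K[0, 2] = K[2, 0] = 0.25  # C(M1, F1)
        kin = KinshipMatrix(ids, K)
        plan = MatingPlan((("M1", "F1"), ("M2", "F2")))
        assert objective_value(plan, parse_strategy("F0"), kin) == pytest.approx(0.25)

    def test_mix_is_weighted_mean_of_components(self):
        kin, eg, males, females = instance(11)
        plan = MatingPlan(((males[0], females[0]), (males[1], females[1]),
                           (males[0], females[2])))
        spec = StrategySpec("mix", "free", 0.5)
        parent = np.mean([kin.get(s, d) for s, d in plan.pairs])
        off = offspring_kinship(plan, kin).values
        off_mean = np.mean([off[a, b] for a, b in itertools.combinations(range(3), 2)])
        expected = 0.5 * parent + 0.5 * off_mean
        assert objective_value(plan, spec, kin) == pytest.approx(expected, abs=1e-12)

    def test_mix_limits_reproduce_pure_family_orderings(self):
        kin, eg, males, females = instance(12)
        rng = np.random.default_rng(0)
        plans = [random_plan(parse_strategy("Ff"), males, females, 4, rng)
                 for _ in range(30)]
        f_vals = [objective_value(p, parse_strategy("Ff"), kin) for p in plans]
        c_vals = [objective_value(p, parse_strategy("Cf"), kin) for p in plans]
        mix1 = [objective_value(p, StrategySpec("mix", "free", 1.0), kin) for p in plans]
        mix0 = [objective_value(p, StrategySpec("mix", "free", 0.0), kin) for p in plans]
        assert np.allclose(mix1, np.array(f_vals) / 4)
        assert np.allclose(mix0, np.array(c_vals) / 6)  # 4 offspring -> 6 pairs


class TestFeasibility:
    def test_one_variant_requires_all_parents(self):
        spec = parse_strategy("F1")
        ok = MatingPlan((("M1", "F1"), ("M2", "F2")))
        bad = MatingPlan((("M1", "F1"), ("M1", "F2")))
        assert feasible(ok, spec, ["M1", "M2"], ["F1", "F2"], 2)
        assert not feasible(bad, spec, ["M1", "M2"], ["F1", "F2"], 2)

    def test_zero_variant_forces_all_dams(self):
        spec = parse_strategy("F0")
        plan = MatingPlan((("M1", "F1"), ("M1", "F2"), ("M1", "F3")))
        assert feasible(plan, spec, ["M1"], ["F1", "F2", "F3"], 3)
        partial = MatingPlan((("M1", "F1"), ("M1", "F1"), ("M1", "F2")))
        reason = check_feasible(partial, spec, ["M1"], ["F1", "F2", "F3"], 3)
        assert "F3" in reason

    def test_harem_constraint(self):
        spec = parse_strategy("Ff")
        shared_dam = MatingPlan((("M1", "F1"), ("M2", "F1"), ("M2", "F2")))
        # F1 served by two sires: forbidden under polygyny, fine without
        assert not feasible(shared_dam, spec, ["M1", "M2"], ["F1", "F2"], 3)
        assert feasible(shared_dam, spec, ["M1", "M2"], ["F1", "F2"], 3, harem=False)
        # distinct sires can never outnumber distinct dams, harem or not
        lopsided = MatingPlan((("M1", "F1"), ("M2", "F1")))
        assert not feasible(lopsided, spec, ["M1", "M2"], ["F1", "F2"], 2, harem=False)

    def test_infeasible_constraints_raise_with_reason(self):
        kin, eg, males, females = instance(13, nm=3, nf=4)
        with pytest.raises(InfeasibleError, match="every female"):
            optimize_plan(parse_strategy("F0"), kin, males, females, 2, eg=eg)
        with pytest.raises(InfeasibleError, match="males"):
            optimize_plan(parse_strategy("Ff"), kin, females, males, 3, eg=eg)


class TestOptimizePlan:
    def test_single_pair_forced(self):
        kin, eg, males, females = instance(1, nm=1, nf=1)
        plan = optimize_plan(parse_strategy("Ff"), kin, males, females, 1, eg=eg)
        assert plan.pairs == ((males[0], females[0]),)

    def test_avoids_related_couple(self):
        ids = ("M1", "M2", "F1", "F2")
        K = np.diag([0.5] * 4)
        K[0, 2] = K[2, 0] = 0.25
        kin = KinshipMatrix(ids, K)
        plan = optimize_plan(parse_strategy("F1"), kin, ["M1", "M2"], ["F1", "F2"], 2)
        assert plan.pairs == (("M1", "F2"), ("M2", "F1"))

    @pytest.mark.parametrize("name", ["F1", "Cf", "dC0", "mixf5-95", "dmFdm1"])
    def test_annealing_matches_exhaustive(self, name):
        spec = parse_strategy(name)
        for seed in range(3):
            kin, eg, males, females = instance(100 + seed, nm=2, nf=3)
            N_t = max(4, spec.dam_floor * 3)
            exact = optimize_plan(spec, kin, males, females, N_t,
                                  method="exact", eg=eg)
            sa = optimize_plan(spec, kin, males, females, N_t,
                               method="anneal", seed=seed, eg=eg)
            assert objective_value(sa, spec, kin, eg=eg) == pytest.approx(
                objective_value(exact, spec, kin, eg=eg), abs=1e-9
            )

    @pytest.mark.parametrize("name", ["F0", "C1", "mix50-50", "dF1"])
    def test_optimum_dominates_random_plans(self, name):
        spec = parse_strategy(name)
        kin, eg, males, females = instance(7)
        N_t = 5
        best = optimize_plan(spec, kin, males, females, N_t, seed=0, eg=eg)
        best_val = objective_value(best, spec, kin, eg=eg)
        rng = np.random.default_rng(42)
        for _ in range(200):
            rp = random_plan(spec, males, females, N_t, rng)
            assert best_val <= objective_value(rp, spec, kin, eg=eg) + 1e-9

    def test_founder_candidates_any_plan_optimal(self, founder_group):
        kin = founder_group.kinship()
        eg = {i: 2.0 for i in kin.ids}
        for spec in all_strategies():
            plan = optimize_plan(spec, kin, ["M1", "M2"], ["F1", "F2"], 2,
                                 seed=1, eg=eg)
            assert objective_value(plan, spec, kin, eg=eg) == pytest.approx(0.0)
            assert feasible(plan, spec, ["M1", "M2"], ["F1", "F2"], 2)

    def test_returned_plans_always_feasible(self):
        for seed, spec in enumerate(all_strategies()):
            kin, eg, males, females = instance(200 + seed, nm=2, nf=3)
            N_t = 4
            plan = optimize_plan(spec, kin, males, females, N_t, seed=seed, eg=eg)
            assert feasible(plan, spec, males, females, N_t)

    def test_exhaustive_tie_break_is_lexicographic(self, founder_group):
        kin = founder_group.kinship()
        plan = optimize_plan(parse_strategy("Ff"), kin, ["M1", "M2"],
                             ["F1", "F2"], 2, method="exact")
        # every plan scores 0; the smallest sorted pair encoding wins
        assert plan.pairs == (("M1", "F1"), ("M1", "F1"))

    def test_determinism_given_seed(self):
        kin, eg, males, females = instance(55)
        a = optimize_plan(parse_strategy("C0"), kin, males, females, 5,
                          seed=9, method="anneal", eg=eg)
        b = optimize_plan(parse_strategy("C0"), kin, males, females, 5,
                          seed=9, method="anneal", eg=eg)
        assert a.pairs == b.pairs

    def test_enumeration_size_guides_auto(self):
        spec = parse_strategy("Ff")
        assert enumeration_size(spec, 2, 2, 2) < 100
        assert enumeration_size(spec, 6, 16, 22) > 1e9
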