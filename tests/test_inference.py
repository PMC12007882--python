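"""Solving engines: minimal-set enumeration, hybrid modes, oracles, stats."""

import pytest

import seedkit as sk
from seedkit.errors import ContractViolation, InputError, SearchRefused
from seedkit.inference import BlockingStore

from conftest import bounded_random_problems, seed_sets


def sets(result):
    return sorted(sorted(s) for s in seed_sets(result))


class TestShrinkToMinimal:
    def test_each_singleton_suffices_on_chain(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning", target_metabolites={"C"})
        minimal = sk.shrink_to_minimal(prob, {"A", "B", "C"})
        assert minimal in ({"A"}, {"B"}, {"C"})

    def test_already_minimal_unchanged(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning", target_metabolites={"C"})
        assert sk.shrink_to_minimal(prob, {"B"}) == {"B"}

    def test_infeasible_superset_is_contract_violation(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning", target_metabolites={"C"})
        with pytest.raises(ContractViolation):
            sk.shrink_to_minimal(prob, set())

    @pytest.mark.parametrize("gen_seed", range(6))
    def test_output_verified_one_minimal_by_deletion(self, gen_seed):
        net = sk.generate_random_network(9, 13, 0.3, 0.25, seed=gen_seed)
        prob = sk.build_problem(net, solve="reasoning")
        minimal = sk.shrink_to_minimal(prob, prob.candidates)
        norm = prob.net
        targets = prob.targets.metabolite_targets
        assert targets <= sk.compute_scope(norm, minimal).reachable
        for m in sorted(minimal - prob.forced_seeds):
            reach = sk.compute_scope(norm, minimal - {m}).reachable
            assert not targets <= reach, f"removing {m} should break feasibility"


class TestReasoning:
    def test_linear3_targets_c_gives_all_singletons(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning", target_metabolites={"C"})
        result = sk.enumerate_reasoning(prob)
        assert sets(result) == [["A"], ["B"], ["C"]]
        assert result.status == "exhausted"

    def test_trap_without_accumulation_check(self, trap):
        prob = sk.build_problem(trap, solve="reasoning")
        assert sets(sk.enumerate_reasoning(prob)) == [["A"], ["B"], ["T"]]

    def test_trap_no_accumulation_excludes_a(self, trap):
        prob = sk.build_problem(trap, solve="reasoning", no_accumulation=True)
        assert sets(sk.enumerate_reasoning(prob)) == [["B"], ["T"]]

    def test_full_network_externals_alone_may_suffice(self, linear3):
        prob = sk.build_problem(linear3, mode="full_network", solve="reasoning",
                                no_accumulation=False)
        result = sk.enumerate_reasoning(prob)
        # A is external (never produced); {A} reaches everything
        assert sets(result) == [["A"]]

    def test_unsatisfiable_reported_distinctly(self, linear3):
        prob = sk.build_problem(
            linear3, solve="reasoning", target_metabolites={"C"},
            forbidden_seeds={"A", "B", "C"},
        )
        result = sk.enumerate_reasoning(prob)
        assert result.status == "unsatisfiable" and not result.solutions
        assert "unreachable" in result.message

    def test_max_solutions_truncates_with_status(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning",
                                target_metabolites={"C"}, max_solutions=2)
        result = sk.enumerate_reasoning(prob)
        assert len(result.solutions) == 2 and result.status == "solution_limit"

    def test_forced_seeds_always_included(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning",
                                target_metabolites={"C"}, forced_seeds={"A"})
        result = sk.enumerate_reasoning(prob)
        assert sets(result) == [["A"]]  # {A} feasible, supersets blocked

    def test_minimize_emits_only_smallest_cardinality(self, trap):
        prob = sk.build_problem(trap, solve="reasoning", optimization="minimize")
        result = sk.enumerate_reasoning(prob)
        assert sets(result) == [["A"], ["B"], ["T"]]  # all size 1 here
        assert all(s.minimality == "cardinality_minimal" for s in result.solutions)


class TestHybridFilter:
    def test_trap_filters_out_a(self, trap):
        prob = sk.build_problem(trap, solve="hybrid_filter")
        result = sk.hybrid_filter(prob)
        assert sets(result) == [["B"], ["T"]]
        assert all(sol.fba_flux > prob.validation.flux_epsilon
                   for sol in result.solutions)

    def test_passthrough_when_everything_validates(self, linear3):
        net = linear3.copy()
        from seedkit.network import Reaction
        net.add_reaction(Reaction("DM_C", {"C": 1.0}, {}, 0.0, 10.0))
        prob_r = sk.build_problem(net, solve="reasoning")
        prob_f = sk.build_problem(net, solve="hybrid_filter")
        assert seed_sets(sk.hybrid_filter(prob_f)) == seed_sets(
            sk.enumerate_reasoning(prob_r)
        )

    def test_total_rejection_flagged(self, accumulation_chain):
        # with the target C forbidden as a seed, every Boolean solution
        # ({A} or {B}) strands the by-product X, so steady state forces a
        # zero objective flux and FBA rejects everything
        prob = sk.build_problem(accumulation_chain, solve="reasoning",
                                forbidden_seeds={"C"})
        assert seed_sets(sk.enumerate_reasoning(prob))  # Boolean layer satisfiable
        filt = sk.build_problem(accumulation_chain, solve="hybrid_filter",
                                forbidden_seeds={"C"})
        filt.candidates = prob.candidates  # restrict to the reasoning pool
        result = sk.hybrid_filter(filt)
        assert result.status == "exhausted_without_valid"
        assert not result.solutions


class TestHybridGC:
    def test_trap_sequence_and_joint_minimality(self, trap):
        prob = sk.build_problem(trap, solve="hybrid_gc")
        result = sk.hybrid_gc(prob)
        assert [sorted(s.seeds) for s in result.solutions] == [["T"], ["B"], ["A", "C"]]
        ac = result.solutions[-1]
        assert ac.minimality == "hybrid_subset_minimal"
        # {A,C} is NOT minimal for the Boolean problem: {A} already reaches T
        norm = prob.net
        assert prob.targets.metabolite_targets <= sk.compute_scope(norm, {"A"}).reachable
        # ...but {A} fails FBA, which is why {A,C} is hybrid-minimal
        assert not sk.validate_seeds_fba(trap, {"A"}, "DM_T")[1]

    def test_agrees_with_reasoning_when_all_validate(self, linear3):
        net = linear3.copy()
        from seedkit.network import Reaction
        net.add_reaction(Reaction("DM_C", {"C": 1.0}, {}, 0.0, 10.0))
        gc = sk.hybrid_gc(sk.build_problem(net, solve="hybrid_gc"))
        reasoning = sk.enumerate_reasoning(sk.build_problem(net, solve="reasoning"))
        assert seed_sets(gc) == seed_sets(reasoning)

    def test_every_emitted_solution_revalidates_independently(self, trap):
        prob = sk.build_problem(trap, solve="hybrid_gc")
        for sol in sk.hybrid_gc(prob).solutions:
            assert prob.targets.metabolite_targets <= sk.compute_scope(
                prob.net, sol.seeds
            ).reachable
            assert sk.validate_seeds_fba(trap, sol.seeds, "DM_T")[1]

    def test_no_duplicates_or_supersets_within_run(self):
        net = sk.generate_random_network(12, 18, 0.3, 0.3, seed=9)
        prob = sk.build_problem(net, solve="hybrid_gc", max_solutions=30)
        result = sk.hybrid_gc(prob)
        emitted = [s.seeds for s in result.solutions]
        assert len(set(emitted)) == len(emitted)
        for i, a in enumerate(emitted):
            for b in emitted[i + 1:]:
                assert not a < b and not b < a


class TestFullHybrid:
    def test_trap_subset_minimal(self, trap):
        prob = sk.build_problem(trap, solve="full_hybrid")
        result = sk.full_hybrid_solve(prob)
        assert sets(result) == [["A", "C"], ["B"], ["T"]]

    def test_trap_minimize_keeps_singletons_only(self, trap):
        prob = sk.build_problem(trap, solve="full_hybrid", optimization="minimize")
        result = sk.full_hybrid_solve(prob)
        assert sets(result) == [["B"], ["T"]]
        assert all(s.minimality == "cardinality_minimal" for s in result.solutions)

    def test_matches_exhaustive_hybrid_gc(self):
        for gen_seed in range(4):
            net = sk.generate_random_network(8, 11, 0.25, 0.3, seed=gen_seed)
            p1 = sk.build_problem(net, solve="full_hybrid", max_solutions=10**6)
            p2 = sk.build_problem(net, solve="hybrid_gc", max_solutions=10**6)
            assert seed_sets(sk.full_hybrid_solve(p1)) == seed_sets(sk.hybrid_gc(p2))

    def test_refuses_large_networks(self):
        net = sk.generate_random_network(80, 210, 0.2, 0.2, seed=0)
        prob = sk.build_problem(net, solve="full_hybrid", max_solutions=1,
                                time_budget=5.0)
        with pytest.raises(SearchRefused):
            sk.full_hybrid_solve(prob)
        # forcing overrides the size envelope (may time out, but must run)
        result = sk.full_hybrid_solve(prob, force=True)
        assert result.status in ("solution_limit", "exhausted", "timeout")


class TestBruteForce:
    def test_linear3_oracle(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning", target_metabolites={"C"})
        assert sk.brute_force_minimal_seed_sets(prob) == {
            frozenset({"A"}), frozenset({"B"}), frozenset({"C"})
        }

    def test_trap_with_fba(self, trap):
        prob = sk.build_problem(trap, solve="hybrid_gc")
        assert sk.brute_force_minimal_seed_sets(prob, with_fba=True) == {
            frozenset({"T"}), frozenset({"B"}), frozenset({"A", "C"})
        }

    def test_infeasible_problem_yields_empty_set(self, linear3):
        prob = sk.build_problem(linear3, solve="reasoning",
                                target_metabolites={"C"},
                                forbidden_seeds={"A", "B", "C"})
        assert sk.brute_force_minimal_seed_sets(prob) == set()

    def test_refuses_oversized_candidate_pools(self):
        net = sk.generate_random_network(30, 45, 0.2, 0.2, seed=1)
        prob = sk.build_problem(net, solve="reasoning")
        if len(prob.candidates - prob.forced_seeds) > 16:
            with pytest.raises(SearchRefused):
                sk.brute_force_minimal_seed_sets(prob)


class TestOracleEquivalence:
    """Exhaustive enumeration equals the brute-force oracle (spot sizes;
    the acceptance suite runs the full 50-network sweeps)."""

    def test_reasoning_matches_oracle(self):
        for _seed, _net, prob in bounded_random_problems(
            "reasoning", 12, 12, dict(n_metabolites=9, n_reactions=13,
                                      reversible_fraction=0.25,
                                      exchange_fraction=0.25)
        ):
            assert seed_sets(sk.enumerate_reasoning(prob)) == \
                sk.brute_force_minimal_seed_sets(prob)

    def test_hybrid_gc_matches_joint_oracle(self):
        for _seed, _net, prob in bounded_random_problems(
            "hybrid_gc", 6, 10, dict(n_metabolites=8, n_reactions=11,
                                     reversible_fraction=0.25,
                                     exchange_fraction=0.3)
        ):
            assert seed_sets(sk.hybrid_gc(prob)) == \
                sk.brute_force_minimal_seed_sets(prob, with_fba=True)


class TestBlockingStore:
    def test_accepted_supersets_and_rejected_exact(self):
        store = BlockingStore()
        store.accept(frozenset({"A"}))
        store.reject(frozenset({"B", "C"}))
        assert store.leaf_blocked(frozenset({"A", "X"}))
        assert store.leaf_blocked(frozenset({"B", "C"}))
        assert not store.leaf_blocked(frozenset({"B", "C", "D"}))  # superset of rejected ok
        assert store.partial_blocked(frozenset({"A", "Y"}))
        assert not store.partial_blocked(frozenset({"B"}))


class TestDeterminismAndDiversity:
    def test_same_configuration_reproduces_solutions(self):
        net = sk.generate_random_network(12, 18, 0.3, 0.3, seed=9)
        runs = []
        for _ in range(2):
            prob = sk.build_problem(net, solve="hybrid_gc_div", max_solutions=8)
            result = sk.hybrid_gc(prob, diversify=True)
            runs.append([sorted(s.seeds) for s in result.solutions])
        assert runs[0] == runs[1]

    def test_diversification_does_not_change_soundness(self):
        net = sk.generate_random_network(12, 18, 0.3, 0.3, seed=9)
        prob = sk.build_problem(net, solve="hybrid_gc_div", max_solutions=8)
        for sol in sk.hybrid_gc(prob, diversify=True).solutions:
            assert prob.targets.metabolite_targets <= sk.compute_scope(
                prob.net, sol.seeds
            ).reachable
            assert sk.validate_seeds_fba(net, sol.seeds, "BIOMASS")[1]

    def test_timeout_yields_flagged_partial_stream(self, trap):
        prob = sk.build_problem(trap, solve="hybrid_gc", time_budget=0.0)
        result = sk.hybrid_gc(prob)
        assert result.status == "timeout"


class TestSolutionStats:
    def test_disjoint_singletons(self, linear3):
        sols = [
            sk.SeedSolution(seeds=frozenset({"A"}), ne_valid=True),
            sk.SeedSolution(seeds=frozenset({"B"}), ne_valid=True),
        ]
        stats = sk.compute_solution_stats(sols, linear3)
        assert stats["union_size"] == 2
        assert stats["frequency"] == {"A": 1, "B": 1}
        assert stats["sizes"] == [1, 1]

    def test_base_id_dereplication(self):
        from seedkit.network import Metabolite, MetabolicNetwork
        net = MetabolicNetwork()
        net.add_metabolite(Metabolite("glc_c", "c"))
        net.add_metabolite(Metabolite("glc_e", "e"))
        sols = [
            sk.SeedSolution(seeds=frozenset({"glc_c"}), ne_valid=True),
            sk.SeedSolution(seeds=frozenset({"glc_e"}), ne_valid=True),
        ]
        stats = sk.compute_solution_stats(sols, net)
        assert stats["union_size"] == 2
        assert stats["dereplicated_union_size"] == 1

    def test_imported_vs_internal_partition(self):
        from seedkit.network import Metabolite, MetabolicNetwork, Reaction
        net = MetabolicNetwork()
        net.add_metabolite(Metabolite("S_e", "e"))
        net.add_metabolite(Metabolite("P_c", "c"))
        net.add_reaction(Reaction("EX_S", {"S_e": 1.0}, {}, -10.0, 1000.0))
        net.add_reaction(Reaction("r", {"S_e": 1.0}, {"P_c": 1.0}, 0.0, 10.0))
        sols = [sk.SeedSolution(seeds=frozenset({"S_e", "P_c"}), ne_valid=True)]
        stats = sk.compute_solution_stats(sols, net)
        assert stats["union_originally_imported"] == ["S_e"]
        assert stats["union_internal"] == ["P_c"]

    def test_empty_list_rejected(self, linear3):
        with pytest.raises(InputError):
            sk.compute_solution_stats([], linear3)

    def test_stats_deterministic_across_runs(self):
        net = sk.generate_random_network(12, 18, 0.3, 0.3, seed=3)
        outs = []
        for _ in range(2):
            prob = sk.build_problem(net, solve="hybrid_gc", max_solutions=6)
            result = sk.hybrid_gc(prob)
            outs.append(sk.compute_solution_stats(result.solutions, net))
        assert outs[0] == outs[1]


class TestProblemConstruction:
    def test_forced_forbidden_overlap_rejected(self, trap):
        with pytest.raises(InputError):
            sk.build_problem(trap, solve="reasoning",
                             forced_seeds={"A"}, forbidden_seeds={"A"})

    def test_hybrid_pool_extends_reasoning_pool(self, trap):
        reasoning = sk.build_problem(trap, solve="reasoning")
        hybrid = sk.build_problem(trap, solve="hybrid_gc")
        assert reasoning.candidates == {"A", "B", "T"}
        assert hybrid.candidates == {"A", "B", "C", "T"}  # C reachable, drainable

    def test_no_accumulation_defaults(self, trap):
        assert not sk.build_problem(trap, solve="reasoning").no_accumulation
        assert sk.build_problem(trap, mode="full_network",
                                solve="reasoning").no_accumulation

    def test_minimize_subset_of_subset_minimal(self, trap):
        subset = sk.build_problem(trap, solve="reasoning")
        minimize = sk.build_problem(trap, solve="reasoning", optimization="minimize")
        assert seed_sets(sk.enumerate_reasoning(minimize)) <= seed_sets(
            sk.enumerate_reasoning(subset)
        )
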