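"""Seed-set solving engines.

The decision problem: find S subseteq M such that the targets are inside
Scope(N, S) — optionally with the no-accumulation surrogate and/or a
positive FBA flux through the objective.  Because any superset of a
solution is a solution, enumeration focuses on *subset-minimal* sets (no
proper subset is feasible), or on *cardinality-minimal* sets under the
``minimize`` optimization.

Engines
-------
reasoning        complete enumeration of subset-minimal seed sets under the
                 Boolean (network-expansion) semantics.
hybrid_filter    reasoning solutions filtered a posteriori by FBA.
hybrid_gc        guess-and-check: each Boolean-minimal candidate failing FBA
                 is blocked exactly (so strict supersets become candidate
                 minimal solutions of the residual problem); accepted sets
                 exclude their supersets.  Emitted sets are subset-minimal
                 for the joint Boolean+FBA problem.
hybrid_gc_div    hybrid_gc with a diversification heuristic that biases the
                 search away from heavily used seeds.
full_hybrid      Boolean and linear constraints solved as one system, with
                 linear feasibility checked on partial assignments; small
                 networks only.

All engines run a complete depth-first branch-and-bound over the candidate
metabolites with blocking constraints (the MARCO-style minimal-set loop:
find a feasible set avoiding blocked regions, shrink it to a true
subset-minimal one, block it, repeat).  Search order is deterministic —
lexicographic, or usage-ordered when diversifying — so runs are
reproducible at a fixed configuration.
"""

from __future__ import annotations

import itertools
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .errors import ContractViolation, InputError, SearchRefused
from .expansion import (
    ScopeEngine,
    SearchMode,
    TargetSet,
    backward_candidates,
    check_no_accumulation,
    derive_targets,
    detect_external_metabolites,
)
from .flux import FBAValidator, ValidationConfig
from .network import BoundaryClass, MetabolicNetwork, classify_boundaries
from .reconciliation import NormalizedNetwork, normalize

logger = logging.getLogger("seedkit")

FULL_HYBRID_MAX_REACTIONS = 200

SOLVE_MODES = ("reasoning", "hybrid_filter", "hybrid_gc", "hybrid_gc_div", "full_hybrid")
HYBRID_MODES = ("hybrid_filter", "hybrid_gc", "hybrid_gc_div", "full_hybrid")


class _Timeout(Exception):
    pass


@dataclass
class SeedProblem:
    net: NormalizedNetwork
    original_net: MetabolicNetwork
    targets: TargetSet
    candidates: FrozenSet[str]
    forced_seeds: FrozenSet[str] = frozenset()
    forbidden_seeds: FrozenSet[str] = frozenset()
    optimization: str = "subset_minimal"  # subset_minimal | minimize
    no_accumulation: bool = False
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    max_solutions: int = 1000
    time_budget: Optional[float] = None
    random_seed: int = 0

    def __post_init__(self):
        if self.optimization not in ("subset_minimal", "minimize"):
            raise InputError(f"unknown optimization {self.optimization!r}")
        if self.max_solutions < 1:
            raise InputError("max_solutions must be >= 1")
        if self.forced_seeds & self.forbidden_seeds:
            raise InputError(
                "forced and forbidden seed sets overlap: "
                f"{sorted(self.forced_seeds & self.forbidden_seeds)}"
            )
        self.candidates = frozenset(
            (self.candidates | self.forced_seeds) - self.forbidden_seeds
        )

    @property
    def objective_for_fba(self) -> Optional[str]:
        return (
            self.original_net.objective_reaction_id
            or self.targets.objective_reaction
        )


@dataclass
class SeedSolution:
    seeds: FrozenSet[str]
    ne_valid: bool
    no_accumulation_valid: Optional[bool] = None
    fba_flux: Optional[float] = None
    minimality: str = "ne_subset_minimal"

    def sorted_seeds(self) -> List[str]:
        return sorted(self.seeds)


@dataclass
class BlockingStore:
    """Blocking constraints injected during enumeration: accepted sets
    exclude all their supersets, rejected sets exclude only themselves."""

    accepted: List[FrozenSet[str]] = field(default_factory=list)
    rejected: List[FrozenSet[str]] = field(default_factory=list)

    def accept(self, s: FrozenSet[str]) -> None:
        self.accepted.append(s)

    def reject(self, s: FrozenSet[str]) -> None:
        self.rejected.append(s)

    def partial_blocked(self, included: FrozenSet[str]) -> bool:
        """True when every completion of ``included`` is a superset of an
        accepted solution."""
        return any(a <= included for a in self.accepted)

    def leaf_blocked(self, s: FrozenSet[str]) -> bool:
        return any(a <= s for a in self.accepted) or any(r == s for r in self.rejected)


@dataclass
class EnumerationResult:
    solutions: List[SeedSolution]
    status: str  # exhausted | solution_limit | timeout | unsatisfiable | exhausted_without_valid
    message: str = ""

    def seed_sets(self) -> Set[FrozenSet[str]]:
        return {sol.seeds for sol in self.solutions}


# ---------------------------------------------------------------------------
# Search engine
# ---------------------------------------------------------------------------


class _Solver:
    def __init__(self, problem: SeedProblem, need_fba: bool):
        self.problem = problem
        self.scope = ScopeEngine(problem.net)
        self.validator: Optional[FBAValidator] = None
        if need_fba:
            objective = problem.objective_for_fba
            if objective is None:
                raise InputError(
                    "hybrid solving requires an objective reaction for FBA validation"
                )
            self.validator = FBAValidator(
                problem.original_net, objective, problem.validation
            )
        self.usage: Counter = Counter()
        self.diversify = False
        self.deadline: Optional[float] = (
            time.monotonic() + problem.time_budget
            if problem.time_budget is not None
            else None
        )

    # -- feasibility ---------------------------------------------------------

    def ne_ok(self, seeds: FrozenSet[str]) -> bool:
        reachable = self.scope.scope(seeds).reachable
        return self.problem.targets.metabolite_targets <= reachable

    def noacc_ok(self, seeds: FrozenSet[str]) -> bool:
        ok, _ = check_no_accumulation(self.problem.net, self.scope.scope(seeds))
        return ok

    def fba_check(self, seeds: FrozenSet[str]) -> Tuple[float, bool]:
        assert self.validator is not None
        return self.validator.check(seeds)

    def feasible(self, seeds: FrozenSet[str], joint: bool) -> bool:
        if not self.ne_ok(seeds):
            return False
        if self.problem.no_accumulation and not self.noacc_ok(seeds):
            return False
        if joint and not self.fba_check(seeds)[1]:
            return False
        return True

    # -- ordering --------------------------------------------------------------

    def order(self, allowed: Iterable[str]) -> List[str]:
        if self.diversify:
            # heavily used seeds first: with exclude-first branching they are
            # dropped preferentially, steering new solutions to fresh content
            return sorted(allowed, key=lambda m: (-self.usage[m], m))
        return sorted(allowed)

    def note_emitted(self, seeds: FrozenSet[str]) -> None:
        self.usage.update(seeds)

    def _tick(self) -> None:
        if self.deadline is not None and time.monotonic() > self.deadline:
            raise _Timeout()

    # -- depth-first feasible-set search --------------------------------------

    def find(
        self,
        allowed: FrozenSet[str],
        store: BlockingStore,
        proper: bool = False,
        joint: bool = False,
        fba_prune: bool = False,
    ) -> Optional[FrozenSet[str]]:
        """First feasible seed set (forced included) drawn from ``allowed``
        that avoids the blocking store.  Branches exclude-first, so small
        sets are reached early; Boolean reachability of the still-possible
        set prunes dead branches (sound: the scope is monotone in the
        seeds), as does FBA on the still-possible set when requested
        (sound: the FBA verdict is monotone under seed supersets)."""
        forced = self.problem.forced_seeds
        order = self.order(allowed - forced)
        n = len(order)
        suffix: List[FrozenSet[str]] = [frozenset()] * (n + 1)
        for i in range(n - 1, -1, -1):
            suffix[i] = suffix[i + 1] | {order[i]}

        def rec(idx: int, included: FrozenSet[str], excluded_any: bool):
            self._tick()
            if store.partial_blocked(included):
                return None
            potential = included | suffix[idx]
            if not self.ne_ok(potential):
                return None
            if fba_prune and not self.fba_check(potential)[1]:
                return None
            if idx == n:
                if proper and not excluded_any:
                    return None
                if store.leaf_blocked(included):
                    return None
                if not self.feasible(included, joint):
                    return None
                return included
            x = order[idx]
            hit = rec(idx + 1, included, True)
            if hit is not None:
                return hit
            return rec(idx + 1, included | {x}, excluded_any)

        return rec(0, frozenset(self.problem.forced_seeds), False)

    def shrink(
        self,
        seeds: FrozenSet[str],
        store: BlockingStore,
        joint: bool = False,
        fba_prune: bool = False,
    ) -> FrozenSet[str]:
        """Reduce ``seeds`` to a set with no feasible, unblocked proper
        subset (hence 1-minimal as well, even under the non-monotone
        no-accumulation constraint)."""
        while True:
            smaller = self.find(
                seeds, store, proper=True, joint=joint, fba_prune=fba_prune
            )
            if smaller is None:
                return seeds
            seeds = smaller

    # -- cardinality-minimal enumeration --------------------------------------

    def minimum_cardinality_sets(
        self, need_fba_pass: bool
    ) -> Tuple[List[Tuple[FrozenSet[str], Optional[float]]], str]:
        """All feasible sets of globally minimal cardinality, by exhaustive
        size-layered search with Boolean-reachability pruning.  Intended for
        small candidate spaces (genome-scale cardinality minimization is out
        of the design envelope)."""
        problem = self.problem
        forced = problem.forced_seeds
        free = self.order(problem.candidates - forced)
        n = len(free)
        for k in range(0, n + 1):
            layer: List[Tuple[FrozenSet[str], Optional[float]]] = []

            def rec(idx: int, included: FrozenSet[str], picked: int):
                self._tick()
                if picked + (n - idx) < k:
                    return
                if not self.ne_ok(included | frozenset(free[idx:])):
                    return
                if picked == k:
                    if self.feasible(included, joint=False):
                        flux: Optional[float] = None
                        if need_fba_pass:
                            flux, ok = self.fba_check(included)
                            if not ok:
                                return
                        layer.append((included, flux))
                    return
                if idx == n:
                    return
                rec(idx + 1, included | {free[idx]}, picked + 1)
                rec(idx + 1, included, picked)

            rec(0, frozenset(forced), 0)
            if layer:
                return layer, "exhausted"
        return [], "unsatisfiable"


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _make_solution(
    solver: _Solver,
    seeds: FrozenSet[str],
    minimality: str,
    fba_flux: Optional[float] = None,
) -> SeedSolution:
    noacc: Optional[bool] = None
    if solver.problem.no_accumulation:
        noacc = solver.noacc_ok(seeds)
    return SeedSolution(
        seeds=seeds,
        ne_valid=solver.ne_ok(seeds),
        no_accumulation_valid=noacc,
        fba_flux=fba_flux,
        minimality=minimality,
    )


def _precheck(solver: _Solver) -> Optional[EnumerationResult]:
    """Short-circuit instances whose full candidate pool cannot reach the
    targets, with a diagnostic naming the unreachable ones."""
    problem = solver.problem
    pool = problem.candidates | problem.forced_seeds
    reachable = solver.scope.scope(pool).reachable
    missing = problem.targets.metabolite_targets - reachable
    if missing:
        return EnumerationResult(
            solutions=[],
            status="unsatisfiable",
            message=f"targets unreachable from the candidate pool: {sorted(missing)[:20]}",
        )
    return None


def shrink_to_minimal(
    problem: SeedProblem, superset: Iterable[str]
) -> FrozenSet[str]:
    """Reduce an NE-feasible superset to a subset-minimal seed set (under
    the problem's no-accumulation flag)."""
    solver = _Solver(problem, need_fba=False)
    s = frozenset(superset) | problem.forced_seeds
    if not s <= problem.candidates | problem.forced_seeds:
        raise ContractViolation("superset contains non-candidate metabolites")
    if problem.forbidden_seeds & s:
        raise ContractViolation("superset contains forbidden seeds")
    if not solver.feasible(s, joint=False):
        raise ContractViolation("superset is not NE-feasible")
    return solver.shrink(s, BlockingStore())


def enumerate_reasoning(problem: SeedProblem) -> EnumerationResult:
    """Complete enumeration of subset-minimal Boolean (NE) seed sets, or of
    all cardinality-minimal sets under the ``minimize`` optimization."""
    solver = _Solver(problem, need_fba=False)
    bad = _precheck(solver)
    if bad is not None:
        return bad

    if problem.optimization == "minimize":
        try:
            layer, status = solver.minimum_cardinality_sets(need_fba_pass=False)
        except _Timeout:
            return EnumerationResult([], "timeout")
        layer.sort(key=lambda t: sorted(t[0]))
        sols = [
            _make_solution(solver, s, "cardinality_minimal")
            for s, _ in layer[: problem.max_solutions]
        ]
        if len(layer) > problem.max_solutions:
            status = "solution_limit"
        return EnumerationResult(sols, status if sols else "unsatisfiable")

    store = BlockingStore()
    solutions: List[SeedSolution] = []
    status = "exhausted"
    try:
        while len(solutions) < problem.max_solutions:
            base = solver.find(problem.candidates, store)
            if base is None:
                break
            seeds = solver.shrink(base, store)
            solutions.append(_make_solution(solver, seeds, "ne_subset_minimal"))
            store.accept(seeds)
            solver.note_emitted(seeds)
        else:
            status = "solution_limit"
    except _Timeout:
        status = "timeout"
    if not solutions and status == "exhausted":
        status = "unsatisfiable"
    return EnumerationResult(solutions, status)


def hybrid_filter(problem: SeedProblem) -> EnumerationResult:
    """Reasoning enumeration filtered a posteriori: only solutions whose
    seed injection yields a positive objective flux are emitted."""
    solver = _Solver(problem, need_fba=True)
    bad = _precheck(solver)
    if bad is not None:
        return bad
    store = BlockingStore()
    emitted: List[SeedSolution] = []
    any_reasoning = False
    status = "exhausted"
    try:
        while len(emitted) < problem.max_solutions:
            base = solver.find(problem.candidates, store)
            if base is None:
                break
            seeds = solver.shrink(base, store)
            store.accept(seeds)
            any_reasoning = True
            flux, ok = solver.fba_check(seeds)
            if ok:
                emitted.append(
                    _make_solution(solver, seeds, "ne_subset_minimal", fba_flux=flux)
                )
                solver.note_emitted(seeds)
        else:
            status = "solution_limit"
    except _Timeout:
        status = "timeout"
    if not emitted and status == "exhausted":
        status = "exhausted_without_valid" if any_reasoning else "unsatisfiable"
    return EnumerationResult(emitted, status)


def hybrid_gc(problem: SeedProblem, diversify: bool = False) -> EnumerationResult:
    """Guess-and-check enumeration of seed sets that are subset-minimal for
    the joint Boolean+FBA problem.

    A Boolean-minimal candidate of the residual problem is produced; if it
    fails FBA, exactly that set is marked inconsistent (its strict supersets
    stay admissible and can become minimal solutions of the residual
    problem); if it passes, it is emitted and all its supersets are
    excluded from future solutions.
    """
    solver = _Solver(problem, need_fba=True)
    solver.diversify = diversify
    bad = _precheck(solver)
    if bad is not None:
        return bad

    if problem.optimization == "minimize":
        return _minimize_with_fba(solver)

    store = BlockingStore()
    emitted: List[SeedSolution] = []
    status = "exhausted"
    try:
        while len(emitted) < problem.max_solutions:
            base = solver.find(problem.candidates, store)
            if base is None:
                break
            seeds = solver.shrink(base, store)
            flux, ok = solver.fba_check(seeds)
            if ok:
                emitted.append(
                    _make_solution(solver, seeds, "hybrid_subset_minimal", fba_flux=flux)
                )
                store.accept(seeds)
                solver.note_emitted(seeds)
            else:
                store.reject(seeds)
        else:
            status = "solution_limit"
    except _Timeout:
        status = "timeout"
    if not emitted and status == "exhausted":
        status = "exhausted_without_valid"
    return EnumerationResult(emitted, status)


def _minimize_with_fba(solver: _Solver) -> EnumerationResult:
    try:
        layer, status = solver.minimum_cardinality_sets(need_fba_pass=True)
    except _Timeout:
        return EnumerationResult([], "timeout")
    layer.sort(key=lambda t: sorted(t[0]))
    problem = solver.problem
    sols = [
        _make_solution(solver, s, "cardinality_minimal", fba_flux=flux)
        for s, flux in layer[: problem.max_solutions]
    ]
    if len(layer) > problem.max_solutions:
        status = "solution_limit"
    return EnumerationResult(sols, status if sols else "unsatisfiable")


def full_hybrid_solve(problem: SeedProblem, force: bool = False) -> EnumerationResult:
    """Boolean reachability and linear feasibility solved as one constraint
    system: the LP is consulted on partial assignments (on the set of still-
    possible seeds, whose verdict is monotone) so infeasible regions are cut
    during search, not after.  Run to exhaustion under subset_minimal this
    emits the same solution set as hybrid_gc.  Refuses networks beyond
    ~200 reactions unless forced: the direct hybrid encoding does not scale
    to genome-sized models."""
    n_reactions = len(problem.net.network.reactions)
    if n_reactions > FULL_HYBRID_MAX_REACTIONS and not force:
        raise SearchRefused(
            f"full_hybrid is limited to {FULL_HYBRID_MAX_REACTIONS} reactions "
            f"(got {n_reactions}); pass force=True to override"
        )
    solver = _Solver(problem, need_fba=True)
    bad = _precheck(solver)
    if bad is not None:
        return bad
    if problem.optimization == "minimize":
        return _minimize_with_fba(solver)

    store = BlockingStore()
    emitted: List[SeedSolution] = []
    status = "exhausted"
    try:
        while len(emitted) < problem.max_solutions:
            base = solver.find(problem.candidates, store, joint=True, fba_prune=True)
            if base is None:
                break
            seeds = solver.shrink(base, store, joint=True, fba_prune=True)
            flux, _ = solver.fba_check(seeds)
            emitted.append(
                _make_solution(solver, seeds, "hybrid_subset_minimal", fba_flux=flux)
            )
            store.accept(seeds)
            solver.note_emitted(seeds)
        else:
            status = "solution_limit"
    except _Timeout:
        status = "timeout"
    if not emitted and status == "exhausted":
        status = "unsatisfiable"
    return EnumerationResult(emitted, status)


def brute_force_minimal_seed_sets(
    problem: SeedProblem, with_fba: bool = False
) -> Set[FrozenSet[str]]:
    """Exhaustive oracle: all subset-minimal feasible seed sets by explicit
    subset enumeration in increasing size.  Refuses more than 16 free
    candidates.  Every feasible set contains a kept (minimal) subset found
    at a smaller size, so skipping supersets of kept sets is exact — also
    under the non-monotone no-accumulation constraint."""
    solver = _Solver(problem, need_fba=with_fba)
    forced = problem.forced_seeds
    free = sorted(problem.candidates - forced)
    if len(free) > 16:
        raise SearchRefused(
            f"brute force limited to 16 free candidates, got {len(free)}"
        )
    kept: List[FrozenSet[str]] = []
    for k in range(0, len(free) + 1):
        for combo in itertools.combinations(free, k):
            s = frozenset(combo) | forced
            if any(m <= s for m in kept):
                continue
            if not solver.feasible(s, joint=False):
                continue
            if with_fba and not solver.fba_check(s)[1]:
                continue
            kept.append(s)
    return set(kept)


# ---------------------------------------------------------------------------
# Solution statistics
# ---------------------------------------------------------------------------


def compute_solution_stats(
    solutions: Sequence[SeedSolution], net: MetabolicNetwork
) -> Dict:
    """Solution-size distribution, union content (also de-replicated at the
    base-molecule level: the same molecule in two compartments counts
    once), per-metabolite frequency, and the split of the union into
    metabolites originally imported by the input model (via an exchange or
    sink) versus internal ones."""
    if not solutions:
        raise InputError("compute_solution_stats requires a nonempty solution list")
    sizes = [len(sol.seeds) for sol in solutions]
    union: Set[str] = set()
    freq: Counter = Counter()
    for sol in solutions:
        union.update(sol.seeds)
        freq.update(sol.seeds)

    base_ids = {net.metabolites[mid].base_id if mid in net.metabolites else mid
                for mid in union}

    classes = classify_boundaries(net)
    imported: Set[str] = set()
    for rid, cls in classes.items():
        if cls in (BoundaryClass.EXCHANGE, BoundaryClass.SINK):
            imported.update(net.reactions[rid].reactants)
    union_imported = sorted(union & imported)
    union_internal = sorted(union - imported)

    return {
        "n_solutions": len(solutions),
        "sizes": sizes,
        "size_min": min(sizes),
        "size_max": max(sizes),
        "size_mean": sum(sizes) / len(sizes),
        "union": sorted(union),
        "union_size": len(union),
        "dereplicated_union_size": len(base_ids),
        "frequency": dict(sorted(freq.items())),
        "union_originally_imported": union_imported,
        "union_internal": union_internal,
    }


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------


def build_problem(
    original_net: MetabolicNetwork,
    mode: SearchMode | str = SearchMode.TARGET,
    solve: str = "reasoning",
    objective: Optional[str] = None,
    target_metabolites: Optional[Iterable[str]] = None,
    forced_seeds: Iterable[str] = (),
    forbidden_seeds: Iterable[str] = (),
    keep_import: bool = False,
    no_accumulation: Optional[bool] = None,
    optimization: str = "subset_minimal",
    validation: Optional[ValidationConfig] = None,
    max_solutions: int = 1000,
    time_budget: Optional[float] = None,
    random_seed: int = 0,
) -> SeedProblem:
    """Normalize the model, derive targets and the candidate pool, and
    assemble a SeedProblem.

    Candidate pool: target mode draws candidates from the backward closure
    of the targets; hybrid solve modes additionally admit every metabolite
    reachable from that closure, so that seeds whose only role is to drain
    an accumulating by-product (via their injected sink) are available to
    FBA repair.  Full-network mode forces the external metabolites and
    draws remaining candidates from the metabolites outside their scope.

    no_accumulation defaults to off in target mode and on in full-network
    mode; the effective value is recorded in the problem.
    """
    mode = SearchMode(mode)
    if solve not in SOLVE_MODES:
        raise InputError(f"unknown solve mode {solve!r}")
    norm = normalize(original_net, keep_import=keep_import)
    forced = frozenset(forced_seeds)
    forbidden = frozenset(forbidden_seeds)
    unknown = (forced | forbidden) - frozenset(original_net.metabolites)
    if unknown:
        raise InputError(f"unknown metabolite id(s) in seed lists: {sorted(unknown)}")

    engine = ScopeEngine(norm)
    if mode is SearchMode.FULL_NETWORK:
        targets = derive_targets(norm, mode)
        external = detect_external_metabolites(norm)
        forced = forced | external
        initial_scope = engine.scope(external).reachable
        candidates = (frozenset(norm.network.metabolites) - initial_scope) | forced
    else:
        obj = objective if target_metabolites is None else frozenset(target_metabolites)
        if obj is None:
            obj = original_net.objective_reaction_id
        if obj is None:
            raise InputError(
                "target mode needs an objective reaction or a target metabolite list"
            )
        targets = derive_targets(norm, mode, obj)
        candidates = backward_candidates(norm, targets)
        if solve in HYBRID_MODES:
            candidates = candidates | engine.scope(candidates | forced).reachable

    if no_accumulation is None:
        no_accumulation = mode is SearchMode.FULL_NETWORK

    return SeedProblem(
        net=norm,
        original_net=original_net,
        targets=targets,
        candidates=candidates,
        forced_seeds=forced,
        forbidden_seeds=forbidden,
        optimization=optimization,
        no_accumulation=no_accumulation,
        validation=validation or ValidationConfig(),
        max_solutions=max_solutions,
        time_budget=time_budget,
        random_seed=random_seed,
    )


def solve(problem: SeedProblem, solve_mode: str, force: bool = False) -> EnumerationResult:
    """Dispatch to the requested engine."""
    if solve_mode == "reasoning":
        return enumerate_reasoning(problem)
    if solve_mode == "hybrid_filter":
        return hybrid_filter(problem)
    if solve_mode == "hybrid_gc":
        return hybrid_gc(problem, diversify=False)
    if solve_mode == "hybrid_gc_div":
        return hybrid_gc(problem, diversify=True)
    if solve_mode == "full_hybrid":
        return full_hybrid_solve(problem, force=force)
    raise InputError(f"unknown solve mode {solve_mode!r}")
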