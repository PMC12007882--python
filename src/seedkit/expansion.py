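"""Boolean producibility on the normalized network.

Network expansion treats a reaction as *activated* once all its reactants
are reachable, regardless of stoichiometric quantities; the *scope* of a
seed set S is the least fixed point

    M0 = S,   M(i+1) = Mi  U  { products(r) : reactants(r) subset of Mi }.

This module also houses the qualitative steady-state surrogate (the
*no-accumulation* check: every scope metabolite must be consumed by at
least one activated reaction), target derivation for the two search modes,
the backward candidate closure from which seeds are drawn, and the
external-metabolite detection used by full-network mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

from .errors import ContractViolation, InputError
from .network import MetabolicNetwork
from .reconciliation import NormalizedNetwork


class SearchMode(str, Enum):
    TARGET = "target"
    FULL_NETWORK = "full_network"


@dataclass
class ScopeResult:
    reachable: FrozenSet[str]
    activated_reactions: FrozenSet[str]
    iterations: int


@dataclass
class TargetSet:
    metabolite_targets: FrozenSet[str]
    objective_reaction: Optional[str]
    mode: SearchMode


class ScopeEngine:
    """Precomputed indexes for repeated scope queries on one network.

    Uses the standard counting algorithm: each reaction tracks how many of
    its reactants are still unreachable; a reaction fires when the count
    hits zero.  Zero-reactant reactions (kept imports 0 -> m) fire in the
    first iteration.  Expansion runs in layers so the iteration count of
    the fixed-point chain is reported.
    """

    def __init__(self, net: NormalizedNetwork):
        self.net = net
        network = net.network
        self.metabolite_ids = frozenset(network.metabolites)
        self._reactants: Dict[str, Tuple[str, ...]] = {}
        self._products: Dict[str, Tuple[str, ...]] = {}
        self._consumed_by: Dict[str, List[str]] = {m: [] for m in network.metabolites}
        for rid in sorted(network.reactions):
            rxn = network.reactions[rid]
            self._reactants[rid] = tuple(sorted(rxn.reactants))
            self._products[rid] = tuple(sorted(rxn.products))
            for mid in rxn.reactants:
                self._consumed_by[mid].append(rid)
        self._scope_cache: Dict[FrozenSet[str], ScopeResult] = {}

    def scope(self, seeds: Iterable[str]) -> ScopeResult:
        seed_set = frozenset(seeds)
        unknown = seed_set - self.metabolite_ids
        if unknown:
            raise InputError(f"unknown seed metabolite id(s): {sorted(unknown)}")
        cached = self._scope_cache.get(seed_set)
        if cached is not None:
            return cached

        remaining = {rid: len(rs) for rid, rs in self._reactants.items()}
        reachable: Set[str] = set(seed_set)
        activated: Set[str] = set()
        frontier = sorted(seed_set)
        # zero-reactant reactions fire immediately (iteration 1)
        ready = [rid for rid, n in remaining.items() if n == 0]
        iterations = 0
        while frontier or ready:
            iterations += 1
            next_ready: List[str] = ready
            ready = []
            for mid in frontier:
                for rid in self._consumed_by[mid]:
                    remaining[rid] -= 1
                    if remaining[rid] == 0:
                        next_ready.append(rid)
            frontier = []
            for rid in next_ready:
                if rid in activated:
                    continue
                activated.add(rid)
                for mid in self._products[rid]:
                    if mid not in reachable:
                        reachable.add(mid)
                        frontier.append(mid)
            frontier.sort()
            if not frontier and not ready:
                break
        result = ScopeResult(
            reachable=frozenset(reachable),
            activated_reactions=frozenset(activated),
            iterations=iterations,
        )
        self._scope_cache[seed_set] = result
        return result


def compute_scope(net: NormalizedNetwork, seeds: Iterable[str]) -> ScopeResult:
    """Least fixed point of the expansion operator from ``seeds``."""
    return ScopeEngine(net).scope(seeds)


def check_no_accumulation(
    net: NormalizedNetwork, scope: ScopeResult
) -> Tuple[bool, List[str]]:
    """True iff every reachable metabolite is a reactant of at least one
    activated reaction; otherwise returns the violating metabolite ids."""
    consumed: Set[str] = set()
    for rid in scope.activated_reactions:
        consumed.update(net.network.reactions[rid].reactants)
    violators = sorted(scope.reachable - consumed)
    return (not violators, violators)


def derive_targets(
    net: NormalizedNetwork,
    mode: Union[SearchMode, str],
    objective: Union[str, Iterable[str], None] = None,
) -> TargetSet:
    """Build the target set for a run.

    Full-network mode targets every metabolite.  Target mode with a reaction
    objective targets the reactants of that reaction in the normalized
    network; with an explicit metabolite list, that list verbatim.
    """
    mode = SearchMode(mode)
    network = net.network
    if mode is SearchMode.FULL_NETWORK:
        return TargetSet(
            metabolite_targets=frozenset(network.metabolites),
            objective_reaction=network.objective_reaction_id,
            mode=mode,
        )
    if objective is None:
        raise InputError("target mode requires an objective reaction or metabolite list")
    if isinstance(objective, str):
        if objective not in network.reactions:
            raise InputError(f"objective reaction {objective!r} not in the network")
        reactants = frozenset(network.reactions[objective].reactants)
        if not reactants:
            raise InputError(
                f"objective reaction {objective!r} has no reactants: nothing to reach"
            )
        return TargetSet(metabolite_targets=reactants, objective_reaction=objective, mode=mode)
    targets = frozenset(objective)
    unknown = targets - frozenset(network.metabolites)
    if unknown:
        raise InputError(f"unknown target metabolite id(s): {sorted(unknown)}")
    if not targets:
        raise InputError("empty target metabolite list")
    return TargetSet(
        metabolite_targets=targets,
        objective_reaction=network.objective_reaction_id,
        mode=mode,
    )


def backward_candidates(net: NormalizedNetwork, targets: TargetSet) -> FrozenSet[str]:
    """Least set containing the targets and, for every reaction producing a
    member, all its reactants.  Every NE-feasible seed set restricted to
    useful seeds is a subset of this closure."""
    if not targets.metabolite_targets:
        raise ContractViolation("backward_candidates requires a nonempty target set")
    producers = net.network.producers_of()
    closure: Set[str] = set()
    stack = sorted(targets.metabolite_targets)
    closure.update(stack)
    while stack:
        mid = stack.pop()
        for rid in producers.get(mid, ()):
            for reactant in net.network.reactions[rid].reactants:
                if reactant not in closure:
                    closure.add(reactant)
                    stack.append(reactant)
    return frozenset(closure)


def _is_transport(net: MetabolicNetwork, rid: str) -> bool:
    """A transport reaction moves the same molecule (shared base_id) between
    two compartments."""
    rxn = net.reactions[rid]
    for mid in rxn.reactants:
        met = net.metabolites[mid]
        for pid in rxn.products:
            pmet = net.metabolites[pid]
            if met.base_id == pmet.base_id and met.compartment != pmet.compartment:
                return True
    return False


def detect_external_metabolites(net: NormalizedNetwork) -> FrozenSet[str]:
    """Metabolites consumed somewhere but produced by no reaction, or
    produced solely through transport reactions.  These initiate the scope
    in full-network mode and are forced as seeds."""
    network = net.network
    producers = network.producers_of()
    consumers = network.consumers_of()
    external: Set[str] = set()
    for mid in network.metabolites:
        if not consumers[mid]:
            continue
        prods = producers[mid]
        if not prods:
            external.add(mid)
        elif all(_is_transport(network, rid) for rid in prods):
            external.add(mid)
    return frozenset(external)


def read_id_list(path: Union[str, Path]) -> FrozenSet[str]:
    """Plain-text metabolite id list: one id per line, '#' comments."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"id-list file not found: {p}")
    ids: Set[str] = set()
    for line in p.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return frozenset(ids)
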