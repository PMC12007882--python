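"""Hand-specified toy networks and a seeded random-network generator.

These are first-class, tested inputs: the toy fixtures have documented
oracle solution sets, and the random generator produces connected networks
whose biomass reactants are guaranteed reachable from the generated
exchange metabolites, so at least one Boolean seed solution always exists.

Fixture catalogue
-----------------
linear3
    A -> B -> C chain, objective B -> C.  With targets {C} every singleton
    is a subset-minimal Boolean solution: {{A}, {B}, {C}}.
trap
    A -> B + C, B -> T, demand T -> 0 (objective).  Seeding {A} reaches T
    but strands C (no consumer): the Boolean solution {A} fails both the
    no-accumulation check and FBA.  Oracles — reasoning: {{T},{B},{A}};
    reasoning + no-accumulation: {{T},{B}}; hybrid: {{T},{B},{A,C}}.
fig1_like
    A small network exercising all four normalization categories
    (reversible split, backwards rewrite, exchange import blocking, [0,0]
    deletion).  Inspired by the usual textbook toy example; it is NOT a
    reproduction of any published figure and carries no asserted solution
    set beyond what the oracles compute.
accumulation_chain
    A -> B + X, B -> C + X, demand C -> 0 (objective): X is produced twice
    and consumed never, so every Boolean path solution accumulates X.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set

import numpy as np

from .errors import InputError
from .network import DEFAULT_BOUND, Metabolite, MetabolicNetwork, Reaction

FIXTURE_NAMES = ("linear3", "trap", "fig1_like", "accumulation_chain")


def _net(
    mets: Dict[str, str],
    rxns: List[Reaction],
    objective: Optional[str],
) -> MetabolicNetwork:
    net = MetabolicNetwork()
    for mid, comp in mets.items():
        net.add_metabolite(Metabolite(id=mid, compartment=comp))
    for rxn in rxns:
        net.add_reaction(rxn)
    net.objective_reaction_id = objective
    net.validate()
    return net


def generate_fixture(name: str) -> MetabolicNetwork:
    if name == "linear3":
        return _net(
            {"A": "c", "B": "c", "C": "c"},
            [
                Reaction("r1", {"A": 1.0}, {"B": 1.0}, 0.0, 10.0),
                Reaction("r2", {"B": 1.0}, {"C": 1.0}, 0.0, 10.0),
            ],
            "r2",
        )
    if name == "trap":
        return _net(
            {"A": "c", "B": "c", "C": "c", "T": "c"},
            [
                Reaction("rxn1", {"A": 1.0}, {"B": 1.0, "C": 1.0}, 0.0, 10.0),
                Reaction("rxn2", {"B": 1.0}, {"T": 1.0}, 0.0, 10.0),
                Reaction("DM_T", {"T": 1.0}, {}, 0.0, 10.0),
            ],
            "DM_T",
        )
    if name == "fig1_like":
        return _net(
            {
                "S1_e": "e",
                "S1_c": "c",
                "A": "c",
                "B": "c",
                "C": "c",
                "D": "c",
                "F": "c",
                "G": "c",
                "H": "c",
            },
            [
                # exchange with an open import: blocked by normalization
                Reaction("EX_S1", {"S1_e": 1.0}, {}, -10.0, DEFAULT_BOUND),
                # transport into the cytosol
                Reaction("T_S1", {"S1_e": 1.0}, {"S1_c": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("R0", {"S1_c": 1.0}, {"A": 1.0}, 0.0, DEFAULT_BOUND),
                # reversible: split into forward/reverse copies
                Reaction("R1", {"A": 1.0}, {"B": 1.0}, -10.0, 100.0),
                # written backwards: rewritten as C -> B
                Reaction("R2", {"B": 1.0}, {"C": 1.0}, -100.0, 0.0),
                # dead bounds: deleted
                Reaction("R3", {"C": 1.0}, {"D": 1.0}, 0.0, 0.0),
                Reaction("R4", {"B": 1.0, "H": 1.0}, {"F": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("OBJ", {"F": 1.0}, {"G": 1.0}, 0.0, DEFAULT_BOUND),
            ],
            "OBJ",
        )
    if name == "accumulation_chain":
        return _net(
            {"A": "c", "B": "c", "C": "c", "X": "c"},
            [
                Reaction("r1", {"A": 1.0}, {"B": 1.0, "X": 1.0}, 0.0, 10.0),
                Reaction("r2", {"B": 1.0}, {"C": 1.0, "X": 1.0}, 0.0, 10.0),
                Reaction("DM_C", {"C": 1.0}, {}, 0.0, 10.0),
            ],
            "DM_C",
        )
    raise InputError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def generate_random_network(
    n_metabolites: int,
    n_reactions: int,
    reversible_fraction: float = 0.2,
    exchange_fraction: float = 0.2,
    seed: int = 0,
) -> MetabolicNetwork:
    """Seeded random network with a reachability guarantee.

    A backbone is laid first: every non-exchange metabolite is produced by a
    reaction whose reactants are already introduced (starting from the
    exchange metabolites), so the whole metabolite set — in particular the
    biomass reactants — is inside the scope of the exchange set.  Extra
    random reactions (1-3 reactants, 1-3 products, small integer
    stoichiometry) fill up to ``n_reactions``; a fraction is reversible.
    Exchange reactions (bounds [-1000, 1000]) and the biomass/demand pair
    are added on top of ``n_reactions``.  Fully determined by ``seed``.
    """
    if n_metabolites < 2 or n_reactions < 1:
        raise InputError("need at least 2 metabolites and 1 reaction")
    n_exchange = max(1, round(exchange_fraction * n_metabolites))
    if n_exchange >= n_metabolites:
        raise InputError("exchange_fraction leaves no internal metabolites")
    if n_reactions < n_metabolites - n_exchange:
        raise InputError(
            "n_reactions too small to introduce every internal metabolite "
            f"(need >= {n_metabolites - n_exchange})"
        )
    rng = np.random.default_rng(seed)
    ids = [f"M{i:02d}" for i in range(n_metabolites)]
    exchange_ids = [str(m) for m in rng.choice(ids, size=n_exchange, replace=False)]
    comp = {mid: ("e" if mid in exchange_ids else "c") for mid in ids}

    net = MetabolicNetwork()
    for mid in ids:
        net.add_metabolite(Metabolite(id=f"{mid}_{comp[mid]}", compartment=comp[mid]))
    full = {mid: f"{mid}_{comp[mid]}" for mid in ids}

    introduced: List[str] = [full[m] for m in exchange_ids]
    pending = [full[m] for m in ids if m not in exchange_ids]
    rng.shuffle(pending)

    def pick(pool: List[str], kmax: int) -> List[str]:
        k = int(rng.integers(1, min(kmax, len(pool)) + 1))
        return [str(m) for m in rng.choice(pool, size=k, replace=False)]

    counter = 0
    for mid in pending:
        reactants = pick(introduced, 3)
        products = [mid]
        rxn = Reaction(
            id=f"R{counter:03d}",
            reactants={m: float(rng.integers(1, 3)) for m in reactants},
            products={m: float(rng.integers(1, 3)) for m in products},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        net.add_reaction(rxn)
        introduced.append(mid)
        counter += 1

    while counter < n_reactions:
        reactants = pick(introduced, 3)
        products = pick([m for m in introduced if m not in reactants], 3)
        rev = bool(rng.random() < reversible_fraction)
        net.add_reaction(
            Reaction(
                id=f"R{counter:03d}",
                reactants={m: float(rng.integers(1, 3)) for m in reactants},
                products={m: float(rng.integers(1, 3)) for m in products},
                lower_bound=-DEFAULT_BOUND if rev else 0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
        counter += 1

    for mid in sorted(exchange_ids):
        net.add_reaction(
            Reaction(
                id=f"EX_{mid}",
                reactants={full[mid]: 1.0},
                products={},
                lower_bound=-DEFAULT_BOUND,
                upper_bound=DEFAULT_BOUND,
            )
        )

    n_bm = int(rng.integers(1, min(3, n_metabolites) + 1))
    bm_reactants = [str(m) for m in rng.choice(sorted(introduced), size=n_bm, replace=False)]
    net.add_metabolite(Metabolite(id="BM_c", compartment="c"))
    net.add_reaction(
        Reaction(
            id="BIOMASS",
            reactants={m: 1.0 for m in bm_reactants},
            products={"BM_c": 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
    )
    net.add_reaction(
        Reaction("DM_BM", {"BM_c": 1.0}, {}, 0.0, DEFAULT_BOUND)
    )
    net.objective_reaction_id = "BIOMASS"
    net.validate()
    return net
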