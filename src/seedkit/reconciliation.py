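"""Model/network reconciliation.

The Boolean (graph) view and the flux view of an SBML model disagree
whenever reactions are reversible or carry negative bounds.  Normalization
rewrites the network so both views agree:

  (i)   reversible reactions (lb < 0 < ub) are split into a forward copy
        [0, ub] and a reverse copy [0, -lb];
  (ii)  reactions running only backwards (ub <= 0, lb < 0) are rewritten in
        the consuming direction;
  (iii) the import direction of exchange and sink reactions is blocked so
        pre-existing media do not leak seeds into the inference — optionally
        kept as an explicit import reaction 0 -> m;
  (iv)  reactions bounded to [0, 0] are deleted.

The stoichiometric-matrix builder lives here too: entries are net gains
(products positive, reactants negative), rows/columns ordered
lexicographically for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
from scipy import sparse

from .network import BoundaryClass, MetabolicNetwork, Reaction, classify_boundaries

logger = logging.getLogger("seedkit")


@dataclass
class NormalizationReport:
    split: int = 0
    reversed: int = 0
    deleted: int = 0
    blocked_imports: int = 0
    kept_imports: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "split": self.split,
            "reversed": self.reversed,
            "deleted": self.deleted,
            "blocked_imports": self.blocked_imports,
            "kept_imports": self.kept_imports,
        }


@dataclass
class NormalizedNetwork:
    """All-irreversible rewrite of a network plus provenance.

    provenance maps each surviving reaction id to
    ``(original_reaction_id, direction)`` with direction in
    {"forward", "reverse"}.  kept_imports lists the optional 0 -> m import
    reactions retained when keep_import was requested.
    """

    network: MetabolicNetwork
    provenance: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    kept_imports: Set[str] = field(default_factory=set)
    report: NormalizationReport = field(default_factory=NormalizationReport)


def _fresh_rev_id(base: str, taken: Set[str]) -> str:
    rid = base + "_rev"
    n = 1
    while rid in taken:
        n += 1
        rid = f"{base}_rev{n}"
    return rid


def normalize(net: MetabolicNetwork, keep_import: bool = False) -> NormalizedNetwork:
    """Rewrite ``net`` so every reaction is irreversible (lb >= 0, ub > 0).

    Idempotent: normalizing an already-normalized network changes nothing.
    The flux polytope is preserved by the split step alone; import blocking
    (applied to exchanges and sinks unless ``keep_import``) deliberately
    removes the import half-reactions.
    """
    classes = classify_boundaries(net)
    out = MetabolicNetwork(
        metabolites=dict(net.metabolites),
        objective_reaction_id=None,
        extracellular_compartments=net.extracellular_compartments,
    )
    provenance: Dict[str, Tuple[str, str]] = {}
    kept: Set[str] = set()
    report = NormalizationReport()
    taken = set(net.reactions)

    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if lb == 0 and ub == 0:
            report.deleted += 1
            continue
        if ub <= 0:
            # written backwards: consumes its declared products
            out.add_reaction(
                Reaction(
                    id=rid,
                    reactants=dict(rxn.products),
                    products=dict(rxn.reactants),
                    lower_bound=max(0.0, -ub),
                    upper_bound=-lb,
                )
            )
            provenance[rid] = (rid, "reverse")
            report.reversed += 1
            continue
        # forward copy (lb clipped at zero if reversible)
        out.add_reaction(
            Reaction(
                id=rid,
                reactants=dict(rxn.reactants),
                products=dict(rxn.products),
                lower_bound=max(0.0, lb),
                upper_bound=ub,
            )
        )
        provenance[rid] = (rid, "forward")
        if lb < 0:
            report.split += 1
            is_import_half = classes[rid] in (BoundaryClass.EXCHANGE, BoundaryClass.SINK)
            if is_import_half and not keep_import:
                report.blocked_imports += 1
                continue
            rev_id = _fresh_rev_id(rid, taken)
            taken.add(rev_id)
            out.add_reaction(
                Reaction(
                    id=rev_id,
                    reactants=dict(rxn.products),
                    products=dict(rxn.reactants),
                    lower_bound=0.0,
                    upper_bound=-lb,
                )
            )
            provenance[rev_id] = (rid, "reverse")
            if is_import_half:
                kept.add(rev_id)
                report.kept_imports += 1

    if net.objective_reaction_id is not None and net.objective_reaction_id in out.reactions:
        out.objective_reaction_id = net.objective_reaction_id
    elif net.objective_reaction_id is not None:
        logger.warning(
            "objective reaction %s did not survive normalization",
            net.objective_reaction_id,
        )
    logger.info("normalization: %s", report.as_dict())
    return NormalizedNetwork(network=out, provenance=provenance, kept_imports=kept, report=report)


@dataclass
class StoichiometricMatrix:
    row_ids: List[str]
    col_ids: List[str]
    matrix: sparse.csc_matrix

    def entry(self, metabolite_id: str, reaction_id: str) -> float:
        i = self.row_ids.index(metabolite_id)
        j = self.col_ids.index(reaction_id)
        return float(self.matrix[i, j])

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def build_matrix(net: MetabolicNetwork) -> StoichiometricMatrix:
    """|M| x |R| net-gain matrix with lexicographic row/column order."""
    rows = sorted(net.metabolites)
    cols = sorted(net.reactions)
    rindex = {m: i for i, m in enumerate(rows)}
    data, ii, jj = [], [], []
    for j, rid in enumerate(cols):
        rxn = net.reactions[rid]
        net_coef: Dict[str, float] = {}
        for mid, coef in rxn.reactants.items():
            net_coef[mid] = net_coef.get(mid, 0.0) - coef
        for mid, coef in rxn.products.items():
            net_coef[mid] = net_coef.get(mid, 0.0) + coef
        for mid, coef in net_coef.items():
            if coef != 0.0:
                data.append(coef)
                ii.append(rindex[mid])
                jj.append(j)
    mat = sparse.csc_matrix(
        (data, (ii, jj)), shape=(len(rows), len(cols)), dtype=float
    )
    return StoichiometricMatrix(row_ids=rows, col_ids=cols, matrix=mat)
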