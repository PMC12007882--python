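"""Linear steady-state layer: FBA, seed injection, and FBA validation.

FBA maximizes (or minimizes) the flux through an objective reaction

    max  v_obj   s.t.   X . v = 0,   vmin <= v <= vmax

with X the stoichiometric net-gain matrix.  Seed validation rebuilds the
*original* model with every pre-existing import closed, reopens or creates
a boundary route for each inferred seed, and asks whether the objective can
carry a positive flux — the numerically accurate counterpart of the Boolean
reachability the solvers work with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .errors import ContractViolation, InputError
from .network import BoundaryClass, MetabolicNetwork, Reaction, classify_boundaries
from .reconciliation import build_matrix

logger = logging.getLogger("seedkit")


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded | error
    objective_flux: float
    fluxes: Dict[str, float]
    message: str = ""


@dataclass
class ValidationConfig:
    """Thresholds for the "positive flux" verdict.

    flux_epsilon separates biological flux from solver noise and must
    dominate lp_tolerance; injected_sink_bounds are the bounds given to the
    boundary reactions created (or reopened) for seeds.
    """

    flux_epsilon: float = 1e-6
    injected_sink_bounds: Tuple[float, float] = (-1000.0, 1000.0)
    lp_tolerance: float = 1e-9

    def __post_init__(self):
        if not self.flux_epsilon > 0:
            raise ContractViolation("flux_epsilon must be positive")
        if not self.flux_epsilon > self.lp_tolerance:
            raise ContractViolation("flux_epsilon must exceed lp_tolerance")
        lo, hi = self.injected_sink_bounds
        if not (lo < 0 < hi):
            raise ContractViolation("injected_sink_bounds must straddle zero")


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_fba(
    net: MetabolicNetwork, objective: str, sense: str = "max"
) -> FluxResult:
    """Solve the FBA linear program with the HiGHS backend."""
    if objective not in net.reactions:
        raise InputError(f"objective reaction {objective!r} not in the network")
    if sense not in ("max", "min"):
        raise InputError(f"sense must be 'max' or 'min', got {sense!r}")
    sm = build_matrix(net)
    n = len(sm.col_ids)
    c = np.zeros(n)
    j = sm.col_ids.index(objective)
    c[j] = -1.0 if sense == "max" else 1.0
    bounds = [
        (net.reactions[rid].lower_bound, net.reactions[rid].upper_bound)
        for rid in sm.col_ids
    ]
    res = linprog(
        c,
        A_eq=sm.matrix,
        b_eq=np.zeros(len(sm.row_ids)),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxResult(status=status, objective_flux=float("nan"), fluxes={}, message=res.message)
    fluxes = {rid: float(res.x[k]) for k, rid in enumerate(sm.col_ids)}
    return FluxResult(
        status="optimal",
        objective_flux=float(fluxes[objective]),
        fluxes=fluxes,
        message=res.message,
    )


# ---------------------------------------------------------------------------
# Seed injection and validation
# ---------------------------------------------------------------------------


def _reopenable_boundary(net: MetabolicNetwork, metabolite_id: str) -> Optional[str]:
    """An exchange-shaped reaction whose import bound can be reopened for an
    extracellular seed: productless, sole participant = the (extracellular)
    seed, positive export capacity.  Matches BiGG models where unused
    exchanges are stored with a closed (zero) import bound."""
    if not net.is_extracellular(metabolite_id):
        return None
    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        if not rxn.products and set(rxn.reactants) == {metabolite_id} and rxn.upper_bound > 0:
            return rid
    return None


def close_imports(net: MetabolicNetwork) -> MetabolicNetwork:
    """Copy of ``net`` with every pre-existing import shut: lower bounds of
    exchange and sink reactions raised to 0 so inferred seeds become the
    model's only inputs."""
    out = net.copy()
    classes = classify_boundaries(net)
    for rid, cls in classes.items():
        if cls in (BoundaryClass.EXCHANGE, BoundaryClass.SINK):
            rxn = out.reactions[rid]
            if rxn.lower_bound < 0:
                rxn.lower_bound = 0.0
    return out


def inject_seeds(
    net: MetabolicNetwork,
    seeds: Iterable[str],
    cfg: ValidationConfig,
) -> MetabolicNetwork:
    """Give every seed a boundary route on the (import-closed) validation
    copy: reopen its exchange reaction if one exists, otherwise create a
    reversible sink m <-> 0 with the configured bounds."""
    out = net.copy()
    lo, hi = cfg.injected_sink_bounds
    for mid in sorted(set(seeds)):
        if mid not in out.metabolites:
            raise InputError(f"unknown seed metabolite id {mid!r}")
        ex = _reopenable_boundary(out, mid)
        if ex is not None:
            rxn = out.reactions[ex]
            rxn.lower_bound = min(rxn.lower_bound, lo)
        else:
            sid = f"SK_seedkit_{mid}"
            n = 1
            while sid in out.reactions:
                n += 1
                sid = f"SK_seedkit_{mid}_{n}"
            out.add_reaction(
                Reaction(
                    id=sid,
                    reactants={mid: 1.0},
                    products={},
                    lower_bound=lo,
                    upper_bound=hi,
                )
            )
    return out


def validate_seeds_fba(
    original_net: MetabolicNetwork,
    seeds: Iterable[str],
    objective: str,
    cfg: Optional[ValidationConfig] = None,
) -> Tuple[FluxResult, bool]:
    """Close all imports on the original (pre-normalization) model, inject
    the seeds, maximize the objective; the verdict is true iff the LP is
    optimal with objective flux above flux_epsilon."""
    cfg = cfg or ValidationConfig()
    if objective not in original_net.reactions:
        raise InputError(f"objective reaction {objective!r} not in the network")
    model = inject_seeds(close_imports(original_net), seeds, cfg)
    result = solve_fba(model, objective, sense="max")
    verdict = result.status == "optimal" and result.objective_flux > cfg.flux_epsilon
    return result, verdict


class FBAValidator:
    """Memoizing wrapper used by the solving engines: one LP per distinct
    seed set per run."""

    def __init__(
        self,
        original_net: MetabolicNetwork,
        objective: str,
        cfg: Optional[ValidationConfig] = None,
    ):
        self.cfg = cfg or ValidationConfig()
        if objective not in original_net.reactions:
            raise InputError(f"objective reaction {objective!r} not in the network")
        self.objective = objective
        self._closed = close_imports(original_net)
        self._cache: Dict[FrozenSet[str], Tuple[float, bool]] = {}
        self.lp_calls = 0

    def check(self, seeds: Iterable[str]) -> Tuple[float, bool]:
        key = frozenset(seeds)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        model = inject_seeds(self._closed, key, self.cfg)
        res = solve_fba(model, self.objective, sense="max")
        self.lp_calls += 1
        flux = res.objective_flux if res.status == "optimal" else 0.0
        verdict = res.status == "optimal" and res.objective_flux > self.cfg.flux_epsilon
        out = (flux, verdict)
        self._cache[key] = out
        return out
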