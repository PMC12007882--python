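# seedkit

Inference of minimal **seed** sets — the nutrients an organism must find in
its environment — from a genome-scale metabolic network (GSMN) and a
metabolic objective. seedkit addresses the *reverse ecology* question: given
only a metabolic reconstruction (SBML), which combinations of external and
internal metabolites make the objective satisfiable? It is aimed at
microbiologists and modellers designing growth media for organisms that are
hard or impossible to culture, where the genome (and hence the GSMN) is
often the only evidence available.

## The model

A GSMN is a set of reactions `r : a1 M1 + … ↔ b1 N1 + …` with flux bounds
`[vmin_r, vmax_r]`. seedkit combines two semantics of "the objective is
satisfiable from seed set S ⊆ M":

* **Network expansion (Boolean).** A reaction activates once *all* its
  reactants are reachable, regardless of quantities; the *scope* is the
  least fixed point
  `Scope(N,S) = ∪ Mi`, `M0 = S`, `M(i+1) = Mi ∪ {products(r) : reactants(r) ⊆ Mi}`.
  S is feasible when the targets (the reactants of the objective reaction,
  or every metabolite in full-network mode) lie in the scope. An optional
  **no-accumulation** surrogate additionally requires every scope
  metabolite to be consumed by at least one activated reaction.
* **Flux balance analysis (linear).** `max v_obj s.t. X·v = 0,
  vmin ≤ v ≤ vmax`, with X the stoichiometric matrix. A seed set is
  FBA-valid when, after closing every pre-existing import and giving each
  seed its own boundary route (reopened exchange or created sink), the
  objective carries a positive flux.

Because any superset of a solution is a solution, seedkit enumerates
**subset-minimal** sets (no proper subset is feasible), or
cardinality-minimal ones on request. Five engines are provided:
`reasoning` (Boolean only, FBA reported a posteriori), `hybrid-filter`
(Boolean solutions filtered by FBA), `hybrid-gc` (guess-and-check: Boolean
minimal candidates failing FBA are blocked exactly, so the emitted sets are
subset-minimal for the joint problem), `hybrid-gc-div` (the same with a
diversification heuristic), and `full-hybrid` (Boolean and linear
constraints solved as one system, small networks only).

## Worked example

The built-in `trap` network is the smallest instance that separates the
semantics: `rxn1: A → B + C`, `rxn2: B → T`, demand `DM_T: T → ∅`
(objective). Seeding `{A}` reaches T through the scope, but the by-product
C is produced and never consumed, so steady state forces zero flux.

```
$ seedkit fixtures trap -o trap.xml
$ seedkit infer trap.xml --mode target --solve hybrid-gc -o trap_gc.json
3 solution(s), status=exhausted -> trap_gc.json
```

`trap_gc.json` then contains (abridged):

```json
"solutions": [
  {"seeds": ["T"],      "ne_valid": true, "fba_flux": 10.0, "minimality": "hybrid_subset_minimal"},
  {"seeds": ["B"],      "ne_valid": true, "fba_flux": 10.0, "minimality": "hybrid_subset_minimal"},
  {"seeds": ["A", "C"], "ne_valid": true, "fba_flux": 10.0, "minimality": "hybrid_subset_minimal"}
]
```

Reading: `{T}` and `{B}` feed the objective directly (flux 10, the shared
bound). The Boolean-minimal set `{A}` was tried, failed FBA, and was
blocked; the guess-and-check loop then found `{A, C}` — seeding C gives it
a sink that drains the accumulation, so the pair is minimal for the joint
problem even though `{A}` alone already satisfies the Boolean one. With
`--solve reasoning` the same model yields `{T}, {B}, {A}` with the
a-posteriori FBA column showing flux 10, 10, 0; with `--no-accumulation`
the Boolean layer itself rejects `{A}`.

The same pipeline is available as a library:

```python
import seedkit as sk
net = sk.generate_fixture("trap")
problem = sk.build_problem(net, solve="hybrid_gc")
result = sk.hybrid_gc(problem)
[sorted(s.seeds) for s in result.solutions]   # [['T'], ['B'], ['A', 'C']]
```

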