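# Methods

## Problem setting

seedkit infers seed metabolites for a genome-scale metabolic network
(GSMN): subsets S of the metabolite set M from which a metabolic objective
becomes satisfiable. Two formalisms are combined. The Boolean one —
network expansion — declares a reaction active once all of its reactants
are reachable and defines the *scope* of S as the least fixed point of
that activation operator; it ignores stoichiometric magnitudes and flux
bounds entirely, which makes it robust on incompletely curated models.
The linear one — flux balance analysis (FBA) — requires a steady-state
flux vector (X·v = 0 within bounds) with positive flux through the
objective reaction; it is numerically accurate but sensitive to model
curation. The Boolean layer over-approximates producibility (it permits
by-product accumulation that steady state forbids), the linear layer
under-constrains reachability (flux may traverse reactions whose
substrates could never be bootstrapped); solutions satisfying both are
the most trustworthy medium predictions.

## Normalization

SBML models routinely disagree between their graph reading and their flux
reading (reversibility flags versus bound signs). Before any inference the
network is rewritten so both views coincide:

1. reversible reactions (vmin < 0 < vmax) are split into a forward copy
   `[0, vmax]` and a reverse copy `[0, −vmin]` (suffix `_rev`, collisions
   resolved with `_revN`);
2. reactions with vmax ≤ 0 run only backwards and are flipped, bounds
   `[max(0, −vmax), −vmin]`;
3. reactions bounded to `[0, 0]` are deleted;
4. the import half of exchange and sink reactions is dropped — otherwise
   the encoded medium would leak free seeds into the inference — unless
   `keep_import` is set, in which case it is retained as an explicit
   `∅ → m` reaction and recorded. Sinks are treated exactly like
   exchanges here; demands only consume and are never import-blocked.

The rewrite is idempotent and, before import blocking, preserves the flux
polytope (checked by LP on random networks). Provenance from every
surviving reaction to its original is kept for reporting. Irreversible
reactions with a strictly positive lower bound keep it in the flux view;
the Boolean view ignores bound magnitudes by construction.

## Target derivation and candidate pools

In **target mode** the targets are the reactants of the objective reaction
(or an explicit metabolite list); in **full-network mode** every
metabolite is a target. Candidates for seeds are restricted without loss
of generality:

* target mode, Boolean engine: the backward closure of the targets
  (targets, plus reactants of any reaction producing a member, to a fixed
  point). Every subset-minimal Boolean solution lives inside this closure.
* target mode, hybrid engines: the closure **plus everything in its
  scope**. The extension is needed because a seed can contribute to a
  hybrid solution purely as a *drain* — its injected sink absorbs an
  accumulating by-product — and such metabolites (e.g. C in the trap
  fixture) are reachable from the closure but not inside it. This is a
  design choice of the package: drains outside that scope are considered
  pathological and are not searched.
* full-network mode: *external* metabolites (consumed somewhere, produced
  by nothing — or produced solely by transport reactions, detected by a
  shared base molecule id across compartments) are forced seeds;
  remaining candidates are the metabolites outside the scope of the
  external set.

Target metabolites are themselves admissible seeds: a target nothing
produces can only be satisfied that way.

The **no-accumulation** option adds the qualitative steady-state
surrogate: every scope metabolite must be consumed by at least one
activated reaction. It defaults to off in target mode and on in
full-network mode; the effective value is echoed in the results document.

## Solving engines

All engines share one deterministic complete search: a depth-first
branch-and-bound over the ordered candidate list, branching exclude-first
(small sets are reached early), pruning any node whose *still-possible*
seed set fails Boolean reachability — sound because the scope is monotone
in the seeds — and, in the full-hybrid engine, any node whose
still-possible set fails FBA (sound because the FBA verdict is monotone
under seed supersets; extra sinks can carry zero flux). Enumeration is
the standard minimal-set loop: find a feasible set avoiding all blocking
constraints, shrink it, block it, repeat until exhaustion, the solution
cap, or the cooperative deadline (partial results are flagged `timeout`,
never silently truncated).

Shrinking searches for a feasible *proper subset* rather than applying a
single deletion pass. This yields true subset-minimality even when
feasibility is non-monotone — which it is under no-accumulation (removing
a seed can empty an unconsumed region of the scope) and under
guess-and-check rejection blocking (a deletion chain may pass through a
rejected set).

* **reasoning** emits Boolean subset-minimal sets; accepted sets block
  all their supersets, so duplicates are impossible. The CLI annotates
  each solution with an a-posteriori FBA verdict when an objective exists.
* **hybrid-filter** runs the same enumeration and emits only solutions
  passing FBA, stopping after `max_solutions` validated ones; exhaustion
  with Boolean solutions but no validated one is reported distinctly
  (`exhausted_without_valid`).
* **hybrid-gc** (guess-and-check) checks FBA *during* solving: a failing
  Boolean-minimal candidate is blocked exactly (strict supersets remain
  admissible and can become minimal solutions of the residual problem);
  a passing one is emitted and blocks its supersets. Emitted sets are
  subset-minimal for the joint problem: run to exhaustion the output
  equals the joint brute-force oracle, which the tests verify on random
  ensembles.
* **hybrid-gc-div** biases the search after each emitted solution:
  candidates are ordered by descending usage count (ties lexicographic),
  so with exclude-first branching the heavily used seeds are dropped
  preferentially and new solutions favour fresh content. Soundness and
  minimality are unaffected — only the exploration order changes.
* **full-hybrid** solves the joint system directly with LP checks on
  partial assignments. It refuses networks beyond 200 reactions unless
  forced: one LP per search node does not scale to genome size, and the
  guess-and-check engine dominates it there.

`minimize` optimization enumerates feasible sets layer-by-layer in
increasing cardinality and emits exactly the sets of the smallest feasible
size (after the FBA pass for hybrid engines); every such set is
automatically subset-minimal. Cardinality minimization is intended for
small networks only.

A brute-force oracle (`brute_force_minimal_seed_sets`, ≤ 16 free
candidates) enumerates all subsets in increasing size, keeping feasible
sets with no kept proper subset; by induction every feasible set contains
a kept subset, so the result is exactly the subset-minimal family — also
under non-monotone constraints. It is the independent reference for the
enumeration engines in the test suite.

## FBA layer and validation

LPs are solved with scipy's HiGHS backend on the lexicographically
ordered stoichiometric matrix. Seed validation runs on the *original*
(pre-normalization) model so stoichiometry and reversibility match the
published semantics: all exchange and sink imports are closed (lower
bounds raised to 0 — sinks import too, so leaving them open would leak
nutrients), then each seed either has its exchange-shaped boundary
reaction reopened or receives a new reversible sink with bounds
`[−1000, 1000]` (the conventional default bound). The classifier itself
is strict — an exchange requires a negative lower bound — but the
reopening step accepts closed (lb = 0) exchange-shaped reactions, the
form BiGG models use for non-medium metabolites, so they are reopened
rather than doubled with sinks. "Positive flux" is decided by maximizing
and thresholding at `flux_epsilon` (default 1e−6, dominating the LP
tolerance 1e−9): strict inequalities are not LP-representable, and
maximize-then-threshold is the standard workaround.

## Synthetic data

The random generator builds connected networks by construction: exchange
metabolites (compartment `e`, reversible exchanges `[−1000, 1000]`) seed a
backbone in which every further metabolite is produced by a reaction over
already-introduced ones; extra random reactions (1–3 reactants, 1–3
products, stoichiometries 1–2, a configurable reversible fraction) are
layered on top, and a biomass reaction over reachable reactants plus its
demand closes the model. Everything is determined by one integer seed.
These networks emulate the *structural* features the algorithms depend on
— branching, reversibility, boundary reactions, by-product traps — but
not the biochemistry of curated GSMNs: no compartments beyond `c`/`e`, no
currency metabolites, no mass conservation, and realistic models are two
orders of magnitude larger. Passing oracle tests therefore certify the
*algorithms* (enumeration completeness, minimality, blocking semantics),
not predictive accuracy on real media.

Test and reference problem sizes are deliberately small so the oracles
stay exhaustive: ensembles of 50 networks with 8–9 metabolites and 11–13
reactions (≤ 10–12 free candidates, ≤ 4096 subsets), and a 14-metabolite,
22-reaction fixture with 44 hybrid solutions for the diversity analysis.

## Numerical and procedural choices

* Search order fixed (lexicographic; usage-ordered when diversifying):
  byte-identical runs at a fixed configuration. The `random_seed`
  configuration value is threaded to every stochastic component (currently
  only the synthetic-data generator; the solver itself is deterministic).
* Scope computed by reactant counting with layered frontiers; results are
  memoized per seed set within a run.
* One LP per distinct seed set per run (memoized), including the partial
  assignments of the full-hybrid engine.
* Timeouts are cooperative deadline checks between search nodes.
* Objectives with several weighted reactions: the largest |coefficient|
  wins, with a warning; a negative coefficient (minimization objective) is
  flagged and treated as the objective reaction.
* Reactions lacking both bounds and a reversibility flag are a format
  error naming the reaction; declared-reversible reactions without bounds
  get `[−1000, 1000]`, irreversible ones `[0, 1000]`.

## Known limitations

* Full-network mode with no-accumulation is the hardest configuration;
  exhaustive enumeration on genome-scale models can exceed any practical
  budget (partial, flagged results are returned).
* The hybrid candidate extension (closure ∪ scope) may miss drain seeds
  reachable only outside the closure's scope; no such case is known in
  the test corpus, and widening the pool to all of M is a one-line
  change at a large search cost.
* Boolean semantics cannot bootstrap self-regenerating cycles (a cycle
  all of whose members require the cycle itself); variants tolerating
  such cycles are out of scope.
* Gene–protein–reaction rules, flux variability, parsimonious and
  loopless FBA are out of scope.
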