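# Methods

## The model

A synthesis graph *G* is a directed bipartite graph over two node kinds:
substances and reactions. An edge *s → r* states that substance *s* is a
reactant or reagent of reaction *r*; an edge *r → s* states that *s* is a
product of *r*. Cycles are permitted — merged retrosynthetic expansions
routinely contain them. Substance metadata consists of two flags and one
optional number: `is_starting_material` (the substance is readily available
from the inventory), `is_target` (the molecule whose synthesis the graph
encodes; exactly one per graph for pruning), and `mw` (molecular weight in
g/mol, used only by inventory inference).

Terminology follows the field: a reaction consuming a substance is the
substance's *child*, a reaction producing it is its *parent*; an
inventory-available substance is a *starting material* even when it sits in
an intermediate position of the graph.

## The pruning cascade

Given an undesirable set *I* (substances forbidden for toxicity,
instability, unavailability, …), pruning must remove every synthesis route
that touches *I* while leaving all other routes intact. The cascade uses
only local, degree-based rules:

1. **Undefined reactions.** A reaction adjacent to a deleted substance is
   deleted, whether the substance was a reactant (the reaction can no
   longer be run) or a product (the reaction must not be run).
2. **Child loss.** A substance that lost a consuming reaction in the
   current batch and now has out-degree 0 is a dead end and is deleted.
   The designated target is exempt: a route terminus has no consumers by
   construction, so child loss can never be evidence against it.
3. **Parent loss.** A substance that lost a producing reaction in the
   current batch, now has in-degree 0, and is *not* a starting material can
   no longer be obtained and is deleted. Starting materials survive parent
   loss — availability from the inventory is exactly what the flag means.
   The target is *not* exempt here: losing every producer legitimately
   propagates, and typically empties the graph.

A substance that lost reactions in both roles within one batch is assessed
under both criteria and deleted if either fires. Loss counts are per
deletion batch, not cumulative across iterations, and a substance never
touched by a batch is never inspected — the rule set is strictly local.

### Step conventions

The trace mirrors the phase granularity of the worked walkthrough: step 1
marks *I*; then each cycle spends one step deleting marked substances and
marking their adjacent reactions, one step marking substances adjacent to
those reactions for inspection, and one step deleting the reactions and
evaluating the inspected substances (marking them for deletion or unmarking
them). The run stops after a deletion step that marks nothing further, or
when the graph empties. A final substance deletion with no adjacent
reactions counts as one step. With *I* = ∅ the run is a single (empty)
marking step and the output equals the input. Each three-step cycle deletes
at least one node, so the step count is bounded by 3·|nodes| + 1.

Iteration order never matters: marks and deletions are computed per batch
over sets, which the order-invariance tests confirm under shuffled node
insertion orders.

### Degenerate inputs and error policy

Undesirable ids absent from the graph are ignored with a warning by default
(block lists are organisation-wide and routinely name substances a given
graph lacks) and rejected under `strict=True`. An id naming a reaction node
is always an error. A graph without a designated target is an error for
pruning; a target inside *I* is allowed, warned about, and empties the
graph. Duplicate edges in input files are collapsed silently with a logged
warning (the model has set semantics). A reaction without a reactant or
product is a validation *warning*, not an error, because pruned
intermediate states legitimately contain such reactions. An empty pruned
graph is a successful outcome ("no viable synthesis route"), distinguished
in the CLI by a machine-readable summary line.

## Viable routes

A *viable route* is an acyclic AND/OR resolution of the target: a substance
is an OR node (one producing reaction is chosen), a reaction is an AND node
(all reactants must be on the route), leaves are starting materials, and no
substance may transitively require itself. Routes are identified by their
reaction set — the substance set follows from it.

Three design points were genuinely open and are resolved as follows:

- **Starting materials are leaves.** A route never selects a producer for a
  non-target starting material, even if the graph contains one (a graph may
  legitimately include synthesis subgraphs converging on an
  inventory-available substance). The alternative — optionally synthesizing
  inventory substances — would change route counts on the worked examples
  and is not enumerated.
- **The target always needs a producer.** Even a target flagged as a
  starting material is only "resolved" by an actual reaction; the empty
  route is never counted.
- **Cycle handling.** During enumeration a producer choice is cut off when
  one of its reactants is already known to require the substance being
  resolved; because cycles can also close across AND-branches, every
  completed selection is re-checked for acyclicity by an independent
  validator before being emitted. Enumeration is therefore exhaustive and
  terminating on cyclic graphs.

Enumeration order is deterministic (lexicographic by sorted reaction ids),
capped at `max_routes` (default 10,000) with an explicit truncation flag.

## Pruning versus the union of surviving routes

The oracle relationship the test suite enforces: discard every viable route
that intersects *I* and merge the survivors (`union_of_routes`); compare
with the cascade's output. On *route-covered* inputs — every node lies on
at least one viable route, which the generator guarantees — the two agree
exactly when the input is acyclic (asserted on 150 random instances, and on
the walkthrough fixture).

Two deliberate limits of that equivalence are worth stating plainly:

- **Cyclic residue.** On cyclic inputs, deleting the only acyclic support
  of a reaction that participates in a directed cycle leaves its local
  degrees untouched, so the degree-based rules keep the mutually
  cycle-supported component even though no acyclic route through it
  survives. The cascade is still *sound* (it never deletes a node of a
  surviving route) and *route-sharp* (the viable routes of its output are
  exactly the surviving routes); the output may merely be a strict superset
  of their union. A minimal frozen counterexample lives in the acceptance
  tests; measured agreement on random cyclic instances is ≈98–100%.
- **Non-route-covered inputs.** A starting material that also has producers
  places those producers off every route, so graphs containing such nodes
  (the inventory-available-intermediate case studies, and the cyclic pair)
  are not route-covered and the union comparison does not apply to them;
  the tests pin their exact expected deletion/retention sets instead.

## Inventory inference

Real reaction corpora lack inventory data, so two heuristics stand in: a
substance with in-degree 0 must come from the inventory, and a substance
lighter than a cutoff (default 200 g/mol, strict inequality) is assumed to
be a purchasable building block. Substances without an `mw` annotation are
skipped by the weight rule. Inference is monotone (never clears a flag) and
idempotent, and both rules can be disabled independently.

## The synthetic generator

The generator emulates the output of a retrosynthetic traversal of a
reaction knowledgebase: a layered expansion below a single target in which
every substance of a layer receives one producing reaction drawing
reactants from the next layer down (reusing pool substances about a third
of the time), plus extra reactions per layer and per-substance alternative
producers (`alt_route_prob`) that create the OR-branching pruning must
navigate. Leaves are always starting materials; interior substances are
flagged inventory-available with probability `sm_fraction`. With
`cycle_prob` > 0, reactions gain back-edge reactants chosen from their own
descendants, which closes directed cycles; each back-edge is kept only if
the graph remains route-covered. Every emitted graph is validated and
route-covered (checked internally with the enumerator; draws that fail —
including draws where an interior inventory flag strands a producer off
every route — are redrawn, with a bounded retry budget).

Defaults (3 layers, 2 reactions per layer, 1–3 reactants per reaction,
sm_fraction 0.2, alt_route_prob 0.3, cycle_prob 0) give graphs of roughly
10–30 substances, the scale of the didactic examples. The property sweeps
use 2–3 layers so brute-force cross-checks stay exhaustive: oracle
comparisons on 200 graphs of ≤30 substances, subset-enumeration checks on
graphs of ≤8 reactions (2⁸ subsets).

What the generator does **not** emulate: real molecule identities and
molecular weights, reagent/catalyst role distinctions, multi-product
reactions (every generated reaction has one product; the model and cascade
handle multi-product reactions, but route semantics for co-products are
only exercised by hand-built tests), and the heavy-tailed degree
distributions of patent-derived knowledgebases. Passing sweeps therefore
demonstrate correctness of the graph logic, not chemical realism.

## Known limitations

- Undesirability is substance-global: a substance unsafe in one reaction
  type is eliminated everywhere (reaction-type-conditional constraints are
  out of scope).
- The variant that also deletes reactions producing a starting material is
  not implemented; multi-product reactions make that criterion ambiguous.
- Pathological inputs outside the route-covered precondition may retain
  dead components, by design of the local rule set (see above).
- XGMML support is a read-only subset (node/edge/att elements); writing is
  GraphML or the CSV edge-list dialect.
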