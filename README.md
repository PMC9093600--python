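# sgp — synthesis graph pruning

Computer-aided synthesis planning merges retro- and forward-synthetic
predictions into a *synthesis graph*: a directed bipartite graph whose two
node kinds are substances and reactions, with substance → reaction edges
for reactants/reagents and reaction → substance edges for products. Such
graphs encode every theoretical pathway to a target molecule — including
pathways a chemist must rule out because they pass through toxic, unstable
or simply unavailable substances.

This package solves that pruning problem for route planners and platform
engineers: given a synthesis graph *G* = (S ∪ R, E) and a set *I* ⊆ S of
undesirable substances, remove every synthesis route that intersects *I*
while leaving all other routes intact. The cascade needs only local rules:

- every substance in *I* is deleted;
- a reaction adjacent to a deleted substance (as reactant **or** product)
  becomes *undefined* and is deleted;
- a substance that lost a consuming reaction and is left with out-degree 0
  is deleted unless it is the target;
- a substance that lost a producing reaction, is left with in-degree 0,
  and is not a starting material (inventory-available) is deleted;

repeated until nothing further is marked or the graph is empty. Inventory
availability is first-class: an intermediate that happens to be in stock
is a starting material and survives the loss of its producers.

The package also provides the brute-force correctness oracle — exhaustive
enumeration of *viable routes* (acyclic AND/OR resolutions of the target
whose leaves are starting materials) and their union — plus a random
route-covered graph generator, transcriptions of the didactic worked
examples, GraphML/XGMML/CSV I/O, and a command-line interface.

## Worked example

The walkthrough graph has 16 substances and 10 reactions; substances `H`
and `I` are undesirable:

```python
>>> import sgp
>>> graph, undesirable = sgp.fixture("fig1")
>>> result = sgp.prune(graph, undesirable)
>>> for line in result.trace_lines():
...     print(line)
step 1 [mark_initial]; marked for deletion: H,I
step 2 [delete_substances_mark_reactions]; deleted: H,I; marked for deletion: 3,5,6
step 3 [mark_inspection]; marked for inspection: E,G,J,M,N
step 4 [delete_reactions_evaluate]; deleted: 3,5,6; marked for deletion: G,M,N; unmarked: E,J
step 5 [delete_substances_mark_reactions]; deleted: G,M,N; marked for deletion: 8,9
step 6 [mark_inspection]; marked for inspection: L,O,T
step 7 [delete_reactions_evaluate]; deleted: 8,9; marked for deletion: L; unmarked: O,T
step 8 [delete_substances_mark_reactions]; deleted: L
>>> result.step_count
8
>>> sorted(result.deleted_nodes)
['3', '5', '6', '8', '9', 'G', 'H', 'I', 'L', 'M', 'N']
>>> sgp.count_routes(result.graph)
1
```

Reading the trace: deleting `H` and `I` undefines reactions 3, 5 and 6;
their surviving neighbours go under inspection. `E` keeps its other
consumer (reaction 4) and is unmarked, while `G` (no consumer left), `M`
and `N` (no producer left, not in stock) cascade onward through reactions
8 and 9 to the leaf `L`. After eight phase-level steps exactly eleven
nodes are gone and the remaining graph is the single viable route *W* to
the target `T` — which `count_routes` confirms.

The same run from the shell:

```console
$ sgp prune -i fig1.graphml -u undesirable.txt -o pruned.graphml --trace trace.json
SGP-RESULT status=pruned steps=8 deleted=11 substances=10 reactions=5
```

An empty result (`status=empty`) is a legitimate answer — it means no
viable synthesis route satisfies the constraints — and still exits 0.
Other subcommands: `sgp routes` (enumerate/count viable routes,
`--via` restricts to routes through a substance), `sgp validate`
(bipartite-invariant check, nonzero exit on violations) and
`sgp generate` (seeded random route-covered graphs):

```console
$ sgp generate --seed 11 --layers 2 -o g.graphml
SGP-GENERATED substances=14 reactions=8 cyclic=false
$ sgp routes -i g.graphml --count-only
2
```

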