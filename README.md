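# netsets

Headless management of **named sets of network nodes and edges** for
exploratory network biology — and for any workflow that asks "which
elements share *these* traits but not *those*?".

A typical use: a protein-interaction network whose node table carries
expression fold-changes for several perturbations. You select the genes
responding to each perturbation, save each selection as a named set, and
then combine the sets — the genes repressed under *every* condition are
simply the intersection of the per-condition sets. `netsets` provides the
machinery around that idea:

* **Set algebra** — union and intersection of any number of sets, and the
  *order-dependent* difference, a strict left fold
  `((S1 \ S2) \ S3) …` over the inputs.
* **Partition** — splits the union of k sets into *membership-signature
  atoms*: each element is grouped by exactly which inputs contain it,
  giving at most `2^k − 1` pairwise-disjoint atoms that cover the union
  (the regions of a Venn diagram, as concrete sets).
* **Set creation** from identifier lists, from the distinct values of a
  string attribute, or by thresholding a numeric attribute
  (e.g. fold change < −0.5).
* **Persistence** — every set is serialized as a boolean column in a
  hidden attribute table (true = member), so membership travels with the
  network and survives a session save/reload; sessions are single-file
  zip bundles of SIF + TSV + JSON manifest that round-trip exactly.
* **Plain-text import/export** of sets (one identifier per line, keyed on
  a chosen id column) with an auditable report of unmatched and ambiguous
  lines.
* **Set-aware layouts** — a *grid of grids* that places each set in its
  own disjoint block, and a seeded force-directed embedder with virtual
  springs between co-set nodes whose strength is a single knob
  (`set_weight`); at `set_weight = 0` it is exactly the plain embedder.
* **A command dispatcher and thin CLI** — the ten scripting commands
  (`createSet`, `addTo`, `removeFrom`, `union`, `intersect`,
  `difference`, `rename`, `remove`, `import`, `export`) with their
  argument names accepted verbatim (`nodeList`, `set1`, `oldName`,
  `setFile`, `Column`, `Type`, …), plus the keywords `selected` and
  `current`.

## Worked example

The built-in synthetic generator emulates a yeast galactose-pathway
screen: a connected 60-node network whose node table has fold-change
columns `gal1RGexp`, `gal4RGexp`, `gal80Rexp` (plus significance
columns), with one gene planted as co-under-expressed and five as
co-over-expressed across all three conditions.

```python
from netsets.fixtures import generate_gal_like, run_expression_workflow

network, tables = generate_gal_like(seed=7)
mgr, pair = run_expression_workflow(network, tables)   # threshold ±0.5
for name in mgr.creation_order:
    print(name, len(mgr.get(name)))
print(pair.down.members, pair.up.members)
```

prints

```
GAL1- 1
GAL1+ 5
GAL4- 1
GAL4+ 5
GAL80- 1
GAL80+ 5
GAL- 1
GAL+ 5
['YSN034W'] ['YSN035W', 'YSN038W', 'YSN046W', 'YSN051W', 'YSN052W']
```

Six condition sets are created by thresholding each column at ±0.5; the
three-way intersection `GAL-` contains the single co-repressed gene and
`GAL+` the five co-induced genes — the planted subsets, recovered purely
by set operations. The same workflow runs from the shell:

```sh
netsets make-fixture fix --seed 7
netsets --session s.zip load-network fix/network.sif
netsets --session s.zip load-attrs fix/node_attrs.tsv
netsets --session s.zip select --column gal1RGexp --relation lt --threshold -0.5
netsets --session s.zip createSet --name GAL1- --nodeList selected
# ... repeat per condition, then:
netsets --session s.zip intersect --name GAL- --set1 GAL1- --set2 GAL4-
```

The `examples/` directory has one short script per capability (algebra,
partition, workflow, import/export, sessions, layouts, commands); each
prints what it computes and says what the numbers mean.

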