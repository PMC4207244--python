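# Methods

## Data model

A `Network` is an undirected graph keyed entirely by name strings: nodes in
first-appearance order, edges as `(source, target, interaction)` records.
Edge identifiers use the SIF-derived display convention
`"source (interaction) target"`; a duplicate record gets the next numeric
suffix (`… #2`, `… #3`), which makes construction order-stable — the same
record list always yields the same identifiers. Records keep their
source/target order for lossless round-tripping even though all algorithms
treat the graph as undirected. Identifier matching is case-sensitive and
exact everywhere; there is no fuzzy mapping.

An `AttributeTable` holds typed columns (string / numeric / boolean) over
one element class, in a `public` or `hidden` namespace. Absent values are
explicit nulls, never sentinel numbers, and a null never satisfies a
threshold relation. The TSV reader auto-types columns: all-parseable →
numeric, all `true`/`false` → boolean, else string.

## Set semantics

A `NamedSet` is homogeneous (node-only or edge-only) and ordered; member
order is first-appearance order of the input, duplicates dropped. The
`SetManager` owns name uniqueness and creation order, and every operation
that produces sets registers its results as ordinary managed sets, so
derived sets participate in later operations and in persistence.

Union and intersection are k-ary and independent of input order up to
member ordering (union: input order then member order; intersection:
first-input order). **Difference is order dependent by design**: a strict
left fold over the inputs in the order given, the only fold consistent
with the two-set case. `remove_from` ignores members not present
(idempotent removal); errors are reserved for unknown sets and node/edge
kind mismatches.

`partition(inputs)` assigns each element of the union its *membership
signature* — the subset of inputs containing it — and registers one atom
per non-empty signature. Atoms are named by joining the included set names
with a separator (default `:`) in creation order; excluded sets are
omitted from the name because the included subset alone determines the
signature. Atom names are validated against the registry *before* any atom
is registered, so a collision leaves the manager untouched. Because a
singleton signature reproduces an input set's own name, callers partition
with a `prefix` (e.g. `"part "`) when the inputs themselves remain
registered; the default empty prefix raises a name-collision error in that
situation rather than silently renaming.

`create_sets_from_attribute` groups elements by the distinct non-null
values of a **string** column (one set per value, named prefix + value);
numeric columns are rejected — thresholding, not grouping, is the numeric
pathway (`select_by_threshold`, relations `lt/le/gt/ge`, nulls excluded,
results in network order).

## Persistence

Each set is serialized as a boolean column named `setsApp::<set name>` in
the hidden table of its element class: true for members, explicit false
for non-members, so an all-false column unambiguously restores an empty
set (empty sets are legal). The namespace prefix guarantees a restore
never resurrects unrelated boolean columns, and a non-boolean column
sitting on a set's slot raises a collision error instead of being
overwritten. Sync is idempotent and drops columns of removed sets;
creation order is persisted as network-level metadata so restored managers
fold differences and name partition atoms identically. Restored member
order is network order (the boolean column cannot carry order) — the only
quantity the table round trip does not preserve; session bundles do
preserve it, via the manifest.

A session bundle is a zip archive of `network.sif`, four attribute TSVs
(public/hidden × node/edge) and `manifest.json` (format version, network
name, node order, edge ids, sets with member order, creation order,
selection, column types). String cells are JSON-quoted in the TSVs so
nulls, empty strings and embedded tabs/newlines round-trip exactly;
numeric cells use `repr(float)` for bit-exact floats. `load(save(x))` is
an exact structural round trip and is verified as such.

## Import/export

One identifier per line; `#` comments, blank lines and surrounding
whitespace tolerated; CRLF accepted, LF written, trailing newline, UTF-8.
Export writes the chosen id column's value per member in member order and
aborts (naming the member) on a null id. Import matches each line exactly
against the id-column values: a line matching several elements (non-unique
column) contributes *all* matches and is flagged ambiguous in the report;
unmatched lines are reported; if nothing matches at all, no set is created.
Export→import is the identity on membership whenever the id column is
unique and non-null.

## Layouts

**Grid of grids.** Each node is owned by the earliest set in creation
order that contains it (creation order being the only canonical order
available when sets overlap); unowned nodes form a trailing block. Within
a block, nodes fill rows of a near-square grid, `columns = ceil(sqrt(m))`,
at pitch `spacing`; blocks sit on an outer near-square grid whose cells
are padded by `2 × spacing` beyond the largest block, so distinct block
bounding boxes are always separated by at least `spacing`. Coordinates are
abstract Cartesian units, y increasing downward.

**Force-directed with set springs.** A Fruchterman–Reingold-style
embedder: all-pairs repulsion `k²/d`, spring attraction `d²/k` along
edges, displacement capped by a linearly cooling temperature
(`t0 = 0.1 × side`), initial positions drawn from a seeded uniform square.
Set awareness adds a virtual spring between every pair of co-set nodes
with strength `set_weight × edge_attraction` and the same rest length as
edge springs; for sets above 50 members the pairs are subsampled to
`50·m` seeded random draws to bound cost at the price of a slightly
noisier (still deterministic) attraction. With `set_weight = 0` the set
pathway is skipped entirely — no arithmetic, no RNG consumption — so the
output is bit-identical to the plain embedder at the same seed. Final
coordinates are centred on the node centroid, removing translation
nondeterminism. Defaults: `set_weight = 1`, `iterations = 100`,
`repulsion = edge_attraction = 1`; 100 iterations comfortably anneals the
tens-of-nodes networks this targets. On the canonical probe (two 5-node
sets joined by one bridge edge, 20 seeds) the mean intra/inter pairwise
distance ratio falls from ≈0.38 at weight 0 to ≈0.16 at weight 5.

## Commands and CLI

The dispatcher exposes exactly ten commands with their argument names
verbatim, including the capitalized `Column` and `Type`; `nodeList` /
`edgeList` take comma-separated identifiers or the keyword `selected`
(the session's selection state, populated by threshold selection), and
`network` takes a name or `current`. When no network is named, the single
loaded network is used; with several loaded and none current, it is an
error. The binary `set1`/`set2` surface is the command interface; k-ary
variants exist only in the library API. Exit codes: 0 success, 2
usage/argument error, 3 domain error. The CLI is a thin layer: each
subcommand builds an argument map and calls the same dispatcher the tests
exercise, with state carried between invocations in a session bundle
(`--session`), and a `batch` mode replaying one command per line in a
single process.

## Synthetic data generator

`generate_gal_like` emulates a deletion-screen expression dataset: a
random spanning tree plus extra random edges (connectivity guaranteed, for
the layout tests), three fold-change columns with companion significance
columns, a planted co-under-expressed subset drawing from
Uniform(−2.0, −0.6), a planted co-over-expressed subset from
Uniform(0.6, 2.0), and background from Uniform(−0.45, 0.45). The gap
around ±0.5 makes recovery by thresholding **deterministic** rather than
probabilistic — that is the point: the generator provides a sharp oracle
for the select→create→intersect workflow, not statistical realism.
Defaults (60 nodes, 90 edges, 1 planted down / 5 planted up — the
intersection sizes the workflow is meant to surface) keep everything
desk-scale. It deliberately does not model microarray noise,
condition-correlated effects, partial responders, or genes crossing the
threshold in some conditions only; passing tests therefore demonstrate the
set machinery, not robustness of the thresholding rule on noisy data.
Significance columns are decorative context (planted genes get small
values), not used by any algorithm.

## Numerical and degenerate-input choices

Layout forces use an `1e-9` epsilon to avoid division by zero for
coincident points; a single-node network maps to the origin; an empty
network to an empty result. Numeric attribute equality in round trips is
exact (values are never re-computed, only re-encoded via `repr`).
Partition of a single set yields one atom (the set itself, under the
prefix). Threshold relations are strict/inclusive exactly as named; the
workflow uses strict `<`/`>` at ±0.5.

## Known limitations

- Sets are bound to one network; there is no cross-network mapping.
- The grid layout ignores edges entirely (by design); the force layout's
  set springs are node-set only — edge sets persist and combine but do not
  influence layout.
- Import matching is exact-string; no case folding or identifier
  translation.
- The CLI session carries a single network; multi-network sessions exist
  only in the in-process API.
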