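# Methods

## The container model

`treelink` implements an experiment container for assay data whose rows
and/or columns are organized by a rooted tree: OTU count tables with a
phylogeny or taxonomy on the features, cytometry marker tables with a
cluster dendrogram on the cells, or any matrix whose entities sit at the
leaves (or internal nodes) of a hierarchy.

A `TreeExperiment` holds:

* **assays** — one or more matrices of identical shape (features × samples);
* **row_data / col_data** — annotation tables aligned to the dimensions;
* **row_tree / col_tree** — optional rooted trees (`Tree` objects);
* **row_links / col_links** — per-entry link records tying each row/column
  to a tree node: `nodeLab` (the node's label), `nodeLab_alias`
  (`alias_{number}`), `nodeNum`, `isLeaf`, and `whichTree` (constant
  `"phylo"`; a single tree per dimension is supported);
* **reference_seqs** — optional per-row sequences (Biopython records).

Links exist iff the corresponding tree exists, and a structural validator
re-checks label/number/leaf-flag coherence after every operation. Several
rows may link to one node; matching is exact, case-sensitive string
equality between the supplied node labels (default: dimension names) and
the tree's labels. The tree takes precedence at construction: unmatched
rows/columns are removed from every aligned component, with a single
warning stating the count.

## Canonical node numbering

Tips are numbered `1..n_tips` in order of appearance in the Newick string;
internal nodes get `n_tips+1 ..` in depth-first preorder (root first,
children in stored order), so the root is always `n_tips + 1`. This is the
numbering convention of the `phylo` ecosystem, and all node-addressed
operations accept either a number or a label ("node reference").

Because numbers change when a tree is pruned, node identity is preserved
across renumbering by *alias tracking*: `track_node` relabels every node
`alias_{number}` under the current numbering; after pruning, the alias can
be looked up in the new tree. `subset_by_leaf` composes
`subset_by_node → keep_tips → track/lookup → change_tree` exactly this way.

## Node algebra

The `Tree` class provides the standard toolkit: descendant/ancestor/child/
sibling queries, lowest common ancestor (`share_node`), descendant-leaf
unions (`union_leaf`), the minimal ancestor representation of a node set
(`join_node`: complete sibling sets are replaced by their parent to a
fixed point, preserving the descendant-leaf union exactly), path distances
(`dist_node`; absent branch lengths count as unit length), tip→root path
tables (`mat_tree`), node labeling (`add_label`, default format
`Node_{number}`), pruning with unary-node suppression and branch-length
summation (`keep_tips`), and collapsing internal nodes into tips
(`as_leaf`). Descendant lists are returned in ascending numeric order;
children in stored order.

## Aggregation

`aggregate` maps each requested target node `v` to one output row (or
column) summarizing its *contributors*: the entries whose linked node lies
in descendant-or-self(`v`) — over all nodes, not only leaves, so entries
linked to internal nodes aggregate upward as well. The reducer (`sum`,
`mean`, `median`, `min`, `max`, `count`, or any list→scalar callable) is
applied independently per opposing-dimension position. Properties that
follow and are verified by tests: targets whose leaf sets partition the
linked leaves conserve column sums under `sum`; overlapping targets each
count shared contributors; entries under no target are silently absent
from the output.

Output dimension names are the alias labels (`alias_{number}`) so they stay
unambiguous when targets are unlabeled; links are rebuilt to point at the
targets. Annotation tables collapse per column: the unanimous contributor
value is kept, disagreement yields a missing value (integer columns are
promoted to a nullable integer type when this introduces missing values).

With `row_block` set to an annotation column, reduction is additionally
restricted within each block value, producing one output row per
(target, block) pair named `alias_{number}.{block}` — the block value is
appended since no canonical format exists for this name. Targets with zero
contributors yield a row of missing values plus a warning, keeping the
requested output shape. When both dimensions are aggregated, `row_first`
selects the order; for linear reducers the results coincide.

## Taxonomy tables and loop resolution

An ordered-rank taxonomy table (broad→fine columns, one row per entity) is
converted to a tree by `to_tree`: leaves carry the finest named value of
each row (unprefixed), internal nodes are labeled `{rank}:{value}`,
identical rank paths merge, all branch lengths are 1, and a single
top-level value becomes the root (multiple top-level values are joined
under a synthetic `ALL` root). Leaves are numbered in depth-first order of
appearance, which equals table row order for tables grouped by taxonomy.
A run of absent cells below a named rank is bridged, so the entity attaches
to its deepest named ancestor.

Conversion requires the table to be free of *polyphyletic loops*: a child
value occurring under two or more distinct parent values in an adjacent
rank pair (an absent value counts as distinct). `detect_loop` reports all
of them; `resolve_loop` suffixes each looping child `_{k}`, numbering the
distinct parents in first-appearance order, processing rank pairs
broad→fine so cascading loops created by a resolution are themselves
resolved in the same pass. A looping *absent* cell is materialized as
`NA_{k}`: this keeps the resolved table loop-free under `detect_loop` at
the cost of introducing placeholder internal nodes, which we prefer to
silently merging distinct lineages. `resolve_loop` is idempotent.

## Serialization

Containers round-trip through plain-text *bundles*: TSV/CSV tables (first
column = row names, missing marker `NA`, numbers at 12 significant
digits), Newick trees (stored child order preserved; labels quoted only
when necessary), FASTA sequences, and a YAML manifest. Link tables are
stored and re-validated on read rather than re-matched, so containers
whose links point at unlabeled nodes (e.g. aggregation outputs) survive a
round trip.

The CLI wraps these: `build`, `aggregate`, `subset`, `tax2tree`,
`tree <op>`, `fixture`. Logging and warnings go to stderr; stdout carries
only data; exit codes are 0 (success), 1 (validation/usage), 2 (I/O).
One CLI convenience: `aggregate --row-level Phylum:B1 ...` on a bundle
whose row tree cannot resolve those labels will construct the taxonomy
tree from the row annotation table and re-link before aggregating — the
same tree swap one performs explicitly in a script.

## Example data and what it covers

`toy_fixture()` builds the worked example used throughout the tests: a
6×4 count matrix (a zero row atop 1..20 filled by column), a 4-rank
taxonomy (Kingdom A; Phyla B1/B2; Classes C1–C3; OTUs D1–D6), sample
annotations (`gg` = 1,2,3,3; `group` = A,A,B,B), a 5-leaf row tree
`((t3,t2),((t1,t5),t4));` to which the six rows map via labels
t3,t3,t2,t1,t5,t4 (two rows share leaf t3), and a column tree
`((sample1,sample2)GroupA,(sample3,sample4)GroupB)All;`.

`random_tree(n, seed)` grows a rooted binary tree by repeatedly splitting
a uniformly chosen tip, with uniform (0, 1] branch lengths — a simple
Yule-type generator adequate for exercising topology-dependent code.
`random_container` links rows to uniformly chosen nodes (leaves *and*
internals) of such a tree. These generators emulate structure, not
biology: counts are homogeneous Poisson draws with no compositional,
phylogenetic or batch signal, so passing tests demonstrate correctness of
the container/tree mechanics, not statistical behavior on real microbiome
or cytometry data.

Property sweeps run on trees of ≤ 12 tips across dozens of seeds, checking
the node algebra against brute-force reachability/path oracles computed
from the raw edge list; the whole suite runs in a few seconds on one CPU.

## Numerical and degenerate-input choices

* Numbers serialize with up to 12 significant digits; round trips are
  exact at that precision.
* Absent branch lengths mean unit lengths in `dist_node`; taxonomy trees
  get explicit unit lengths.
* A pruned tree's suppressed unary nodes contribute their branch length to
  the retained child; the pruned root carries no length.
* `as_leaf` refuses unlabeled nodes (a tip must carry a label) and nested
  targets.
* `change_tree` matching zero entries raises rather than returning an
  empty container; zero-row *subsets* are legal and render fine.
* Duplicate assay row names are tolerated (positions, not names, drive all
  subsetting); tip labels must be unique and non-empty, internal labels
  unique where present.

## Known limitations

* One tree per dimension (`whichTree` is the constant `"phylo"`).
* Reducers are per-position list→scalar; matrix-level reducers and
  parallel evaluation are not supported.
* Row aggregation drops reference sequences (an aggregated row has no
  single sequence).
* Dense in-memory matrices only; no sparse or on-disk backends.
* `find_ancestor` walks a fixed number of edges rootward (default 1)
  rather than returning the whole chain; ordering of all-descendant
  queries is ascending numeric.
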