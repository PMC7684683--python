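# treelink

Tree-linked assay containers for hierarchical experiment data.

Biological assay matrices often come with a hierarchy on their rows or
columns: OTU count tables with a phylogeny or taxonomy over the features,
cytometry marker tables with a dendrogram over cell clusters, sample sets
grouped into nested conditions. `treelink` stores such data as a single
object — named assay matrices, row/column annotation tables, optional
rooted trees on either dimension, and automatically maintained *link
tables* tying every row/column to a tree node — and lets you subset,
re-tree, prune and aggregate the data at arbitrary resolutions of the
hierarchy without the links ever going stale.

Core pieces:

* **`Tree`** — rooted labeled trees with the canonical numbering of the
  `phylo` ecosystem (tips `1..n` in order of appearance, internals in
  preorder, root = `n_tips + 1`), Newick I/O, and a node-algebra toolkit:
  descendants, ancestors, siblings, lowest common ancestor, descendant-leaf
  unions, minimal ancestor representations (`join_node`), node distances,
  path tables, labeling, alias tracking, pruning, and collapsing branches
  into leaves.
* **`TreeExperiment`** — the container, with construction by label
  matching (unmatched entries dropped with a warning), lockstep subsetting
  by index or by node, tree replacement (`change_tree`), leaf subsetting
  with pruning (`subset_by_leaf`), reference sequences, and text-bundle
  serialization.
* **`aggregate`** — reduce assay values to any set of target nodes, per
  row, column or both, with per-block reduction and annotation collapse.
* **taxonomy tools** — convert ordered-rank taxonomy tables to trees
  (`to_tree`), detecting and resolving polyphyletic loops
  (`detect_loop` / `resolve_loop`).
* **`treelink` CLI** — the same operations on TSV/CSV + Newick files.

## Worked example

The built-in toy container has counts of 6 entities in 4 samples, a 4-rank
taxonomy on the rows, a 5-leaf row tree (two rows map to the same leaf
`t3`), and a column tree grouping the samples into GroupA/GroupB.

```python
import statistics
from treelink import toy_fixture, toy_taxonomy, to_tree

toy = toy_fixture()
print(toy.row_links)
#         nodeLab nodeLab_alias  nodeNum  isLeaf whichTree
# entity1      t3       alias_1        1    True     phylo
# entity2      t3       alias_1        1    True     phylo
# entity3      t2       alias_2        2    True     phylo
# entity4      t1       alias_3        3    True     phylo
# entity5      t5       alias_4        4    True     phylo
# entity6      t4       alias_5        5    True     phylo

# swap the row tree for the taxonomy tree, matching rows via the OTU column
taxa = toy_taxonomy()
toy_taxa = toy.change_tree(row_tree=to_tree(taxa),
                           row_node_labels=list(taxa["OTU"]))

# sum counts to the two phylum nodes (nodes 8 and 10 of the taxonomy tree)
agg = toy_taxa.aggregate(row_level=["Phylum:B1", "Phylum:B2"],
                         row_reducer=sum)
print(agg.assay())
#           sample1  sample2  sample3  sample4
# alias_8       1.0      6.0     11.0     16.0
# alias_10     14.0     34.0     54.0     74.0

# aggregate both dimensions: sample groups by mean, then row nodes by sum
both = toy.aggregate(row_level=[7, 8, 9], row_reducer=sum,
                     col_level=[6, 7], col_reducer=statistics.fmean,
                     row_first=False)
print(both.assay())
#          alias_6  alias_7
# alias_7      8.0     28.0
# alias_8     19.5     49.5
# alias_9     12.0     32.0
```

Each output row/column is named by the target node's alias
(`alias_{number}`); its link table points at the target nodes, and the
annotation tables collapse to the values its contributors agree on.
Subsetting keeps everything aligned:

```python
sub = toy.subset_by_leaf(["t2", "t3"])   # 3 rows; row tree pruned
print(sub.n_rows, sub.row_tree.n_tips)   # 3 2
```

The same pipeline from the shell:

```sh
treelink fixture toy -o toy_bundle
treelink aggregate toy_bundle --row-level Phylum:B1 Phylum:B2 --row-fun sum
treelink tree convert --tree toy_bundle/col_tree.nwk GroupA GroupB   # -> 6 7
```

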