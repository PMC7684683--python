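"""Deterministic example data: the six-entity toy container and seeded
random trees/containers for property testing.

The toy container mimics a minimal microbiome survey: counts of 6 entities
(OTUs) in 4 samples, a 4-rank taxonomy on the rows, a 5-leaf row tree to
which the six rows map (two rows share the leaf ``t3``), and a 4-leaf
column tree grouping the samples into GroupA/GroupB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .container import TreeExperiment, build
from .tree import Tree, _N, parse_newick

__all__ = [
    "toy_fixture",
    "toy_taxonomy",
    "ROW_TREE_NEWICK",
    "COL_TREE_NEWICK",
    "ROW_NODE_LABELS",
    "random_tree",
    "random_container",
]

ROW_TREE_NEWICK = "((t3,t2),((t1,t5),t4));"
COL_TREE_NEWICK = "((sample1,sample2)GroupA,(sample3,sample4)GroupB)All;"
ROW_NODE_LABELS = ["t3", "t3", "t2", "t1", "t5", "t4"]


def toy_taxonomy() -> pd.DataFrame:
    """The toy 4-rank taxonomy table (Kingdom/Phylum/Class/OTU)."""
    return pd.DataFrame(
        {
            "Kingdom": ["A"] * 6,
            "Phylum": ["B1", "B1", "B2", "B2", "B2", "B2"],
            "Class": ["C1", "C1", "C2", "C2", "C3", "C3"],
            "OTU": [f"D{i}" for i in range(1, 7)],
        },
        index=[f"entity{i}" for i in range(1, 7)],
    )


def toy_fixture() -> TreeExperiment:
    """The toy container: a 6x4 count matrix with both trees attached."""
    assay = pd.DataFrame(
        np.vstack([np.zeros(4, dtype=int),
                   np.arange(1, 21).reshape(4, 5).T]),
        index=[f"entity{i}" for i in range(1, 7)],
        columns=[f"sample{i}" for i in range(1, 5)],
    )
    col_data = pd.DataFrame(
        {"gg": [1, 2, 3, 3], "group": ["A", "A", "B", "B"]},
        index=assay.columns,
    )
    return build(
        assays={"Count": assay},
        row_table=toy_taxonomy(),
        col_table=col_data,
        row_tree=parse_newick(ROW_TREE_NEWICK),
        col_tree=parse_newick(COL_TREE_NEWICK),
        row_node_labels=ROW_NODE_LABELS,
    )


def random_tree(n_tips: int, seed) -> Tree:
    """Random rooted binary tree grown by repeated tip splitting.

    Starting from a single tip, a uniformly chosen tip is split into two
    children until ``n_tips`` tips exist; every edge gets a uniform (0, 1]
    branch length.  Tips are labeled ``t1..tn`` in order of appearance and
    internal nodes are unlabeled.  Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("random_tree requires n_tips >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    root = _N()
    tips = [root]
    while len(tips) < n_tips:
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        node.children = [_N(length=float(1.0 - rng.random())),
                         _N(length=float(1.0 - rng.random()))]
        tips.extend(node.children)
    if not root.children:  # n_tips == 1 is excluded above, keep guard
        raise AssertionError
    # label tips in depth-first order of appearance
    counter = [0]

    def label(n: _N) -> None:
        if not n.children:
            counter[0] += 1
            n.label = f"t{counter[0]}"
        for c in n.children:
            label(c)

    label(root)
    return Tree(root)


def random_container(n_rows: int, n_cols: int, seed) -> TreeExperiment:
    """Random container with rows linked to uniformly chosen nodes (leaves
    and internals) of a random row tree; columns link to the leaves of a
    random column tree by name.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    n_row_tips = max(2, (n_rows + 1) // 2)
    row_tree = random_tree(n_row_tips, rng).add_label(on="internal")
    col_tree = random_tree(max(2, n_cols), rng)

    row_names = [f"feature{i}" for i in range(1, n_rows + 1)]
    col_names = [f"obs{i}" for i in range(1, n_cols + 1)]
    # rename column-tree tips to the first n_cols observation names
    col_tree = Tree.from_newick(col_tree.to_newick())
    relabel = dict(zip([f"t{i}" for i in range(1, col_tree.n_tips + 1)],
                       col_names))
    root, by_num = col_tree._copy_nodes()
    for num, node in by_num.items():
        if col_tree.is_tip(num):
            node.label = relabel[node.label]
    col_tree = Tree(root)

    row_nodes = rng.integers(1, row_tree.n_nodes + 1, size=n_rows)
    row_labels = [row_tree.label(int(v)) for v in row_nodes]
    assay = pd.DataFrame(
        rng.poisson(10.0, size=(n_rows, n_cols)),
        index=row_names, columns=col_names,
    )
    row_data = pd.DataFrame(
        {"group": rng.choice(["A", "B"], size=n_rows)}, index=row_names
    )
    col_data = pd.DataFrame(
        {"batch": rng.choice([1, 2], size=n_cols)}, index=col_names
    )
    return build(
        assays={"Count": assay},
        row_table=row_data,
        col_table=col_data,
        row_tree=row_tree,
        col_tree=col_tree,
        row_node_labels=row_labels,
        col_node_labels=col_names[: n_cols],
    )
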