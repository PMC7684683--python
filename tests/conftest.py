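import pandas as pd
import pytest

from treelink import parse_newick, to_tree, toy_fixture, toy_taxonomy
from treelink.fixtures import COL_TREE_NEWICK, ROW_TREE_NEWICK


@pytest.fixture
def col_tree():
    return parse_newick(COL_TREE_NEWICK)


@pytest.fixture
def row_tree():
    return parse_newick(ROW_TREE_NEWICK)


@pytest.fixture
def toy():
    return toy_fixture()


@pytest.fixture
def taxa_table():
    return toy_taxonomy()


@pytest.fixture
def taxa_tree():
    return to_tree(toy_taxonomy())


@pytest.fixture
def toy_taxa(toy, taxa_tree, taxa_table):
    """The toy container re-linked to the taxonomy tree via the OTU column."""
    return toy.change_tree(row_tree=taxa_tree,
                           row_node_labels=list(taxa_table["OTU"]))


# ----------------------------------------------------------------------
# brute-force oracles, independent of the Tree implementation paths:
# they work purely on the parent/child edge list extracted as data
# ----------------------------------------------------------------------

def edges_of(tree):
    """(parent, child) pairs of a tree, as plain data."""
    return [(p, c) for p in range(1, tree.n_nodes + 1)
            for c in tree._children[p]]


def bf_descendants(edges, node, tips):
    """Reachability by repeated expansion over the edge list."""
    out = set()
    frontier = {node}
    while frontier:
        new = {c for (p, c) in edges if p in frontier}
        new -= out
        out |= new
        frontier = new
    return out


def bf_root_path(edges, node):
    parent = {c: p for (p, c) in edges}
    path = [node]
    while path[-1] in parent:
        path.append(parent[path[-1]])
    return path


def bf_share(edges, nodes):
    paths = [bf_root_path(edges, n) for n in nodes]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    for v in paths[0]:
        if v in common:
            return v


def bf_union_leaf(edges, nodes, tips):
    out = set()
    for n in nodes:
        desc = bf_descendants(edges, n, tips) | {n}
        out |= {v for v in desc if v in tips}
    return sorted(out)
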