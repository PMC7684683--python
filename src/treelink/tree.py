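"""Rooted labeled trees with canonical node numbering and node algebra.

The :class:`Tree` class stores a rooted tree under the numbering convention
used throughout the microbiome/phylogenetics ecosystem: tips are numbered
``1..n_tips`` in their order of appearance in the Newick string, internal
nodes are numbered ``n_tips+1 ..`` in depth-first preorder (root first,
children in stored order), so the root is always ``n_tips + 1``.  Node
numbers are therefore stable for a given topology and child order, and every
operation that returns a new tree recomputes them canonically.

Nodes are addressed uniformly by *node reference*: either a node number
(integer) or a node label (string).  Tip labels are mandatory and unique;
internal labels are optional but, where present, unique among all labels.
"""

from __future__ import annotations

import io
import numbers
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import pandas as pd

from .errors import NewickParseError, NodeResolveError, ValidationError

NodeRef = Union[int, str]

__all__ = ["Tree", "NodeRef", "parse_newick", "write_newick"]


@dataclass
class _N:
    """Mutable construction node used to assemble trees before numbering."""

    label: Optional[str] = None
    length: Optional[float] = None
    children: list = field(default_factory=list)


def _fmt_len(x: float) -> str:
    return format(float(x), ".12g")


def _quote_label(lab: str) -> str:
    if any(c in lab for c in "(),:;[]' \t\n"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


class Tree:
    """A rooted labeled tree with canonical node numbering.

    Instances are immutable in practice: all manipulating operations
    (:meth:`keep_tips`, :meth:`add_label`, ...) return new trees.
    """

    def __init__(self, root: _N):
        tips: list[_N] = []
        internals: list[_N] = []

        stack = [root]
        order: list[_N] = []
        # iterative DFS preorder; recursion would overflow on deep trees
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(reversed(n.children))
        for n in order:
            (internals if n.children else tips).append(n)

        self.n_tips = len(tips)
        self.n_internal = len(internals)
        num_of: dict[int, int] = {}
        for i, n in enumerate(tips):
            num_of[id(n)] = i + 1
        for j, n in enumerate(internals):
            num_of[id(n)] = self.n_tips + 1 + j

        self.tip_labels: list[str] = [n.label or "" for n in tips]
        self.internal_labels: list[Optional[str]] = [n.label for n in internals]

        children: dict[int, tuple[int, ...]] = {}
        parent: dict[int, int] = {}
        lengths: dict[int, float] = {}
        for n in order:
            num = num_of[id(n)]
            children[num] = tuple(num_of[id(c)] for c in n.children)
            for c in n.children:
                parent[num_of[id(c)]] = num
            if n.length is not None and id(n) != id(root):
                lengths[num] = float(n.length)
        self._children = children
        self._parent = parent
        self.branch_lengths: Optional[dict[int, float]] = lengths or None

        self._validate()
        self._label_to_num = {}
        for i, lab in enumerate(self.tip_labels):
            self._label_to_num[lab] = i + 1
        for j, lab in enumerate(self.internal_labels):
            if lab is not None:
                self._label_to_num[lab] = self.n_tips + 1 + j

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------

    def _validate(self) -> None:
        for lab in self.tip_labels:
            if not lab:
                raise ValidationError("tip labels must be non-empty")
        all_labels = list(self.tip_labels) + [
            l for l in self.internal_labels if l is not None
        ]
        if len(set(all_labels)) != len(all_labels):
            dupes = sorted({l for l in all_labels if all_labels.count(l) > 1})
            raise ValidationError(f"duplicate node labels: {dupes}")
        if self.branch_lengths is not None:
            for num, x in self.branch_lengths.items():
                if x < 0:
                    raise ValidationError(
                        f"negative branch length {x} on edge to node {num}"
                    )

    @property
    def n_nodes(self) -> int:
        return self.n_tips + self.n_internal

    @property
    def root(self) -> int:
        return self.n_tips + 1 if self.n_internal else 1

    def is_tip(self, num: int) -> bool:
        return 1 <= num <= self.n_tips

    def children(self, node: NodeRef) -> tuple[int, ...]:
        return self._children[self.resolve(node)]

    def parent(self, node: NodeRef) -> Optional[int]:
        return self._parent.get(self.resolve(node))

    def label(self, num: int) -> Optional[str]:
        """Label of node ``num``, or None for an unlabeled internal node."""
        if self.is_tip(num):
            return self.tip_labels[num - 1]
        return self.internal_labels[num - self.n_tips - 1]

    def alias(self, num: int) -> str:
        """The synthetic ``alias_{number}`` label of a node."""
        self.resolve(num)
        return f"alias_{num}"

    def resolve(self, ref: NodeRef) -> int:
        """Resolve a node reference (number or label) to a node number."""
        if isinstance(ref, bool):
            raise NodeResolveError(ref)
        if isinstance(ref, numbers.Integral):
            num = int(ref)
            if not 1 <= num <= self.n_nodes:
                raise NodeResolveError(num)
            return num
        if isinstance(ref, str):
            try:
                return self._label_to_num[ref]
            except KeyError:
                raise NodeResolveError(ref) from None
        raise NodeResolveError(ref)

    def labels(self) -> set[str]:
        """All labels present in the tree (tips and labeled internals)."""
        return set(self._label_to_num)

    def edge_length(self, child_num: int) -> float:
        """Length of the edge above ``child_num``; 1.0 where absent."""
        if self.branch_lengths is None:
            return 1.0
        return self.branch_lengths.get(child_num, 1.0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return (
            self.tip_labels == other.tip_labels
            and self.internal_labels == other.internal_labels
            and self._children == other._children
            and self.branch_lengths == other.branch_lengths
        )

    def __repr__(self) -> str:
        return (
            f"<Tree with {self.n_tips} tips and {self.n_internal} "
            f"internal nodes>"
        )

    # ------------------------------------------------------------------
    # node algebra
    # ------------------------------------------------------------------

    def convert_node(self, nodes: Sequence[NodeRef], to: str = "label") -> list:
        """Translate node references to labels or numbers, order-preserving.

        With ``to="label"`` an unlabeled internal node converts to ``None``.
        """
        if to == "number":
            return [self.resolve(n) for n in nodes]
        if to == "label":
            return [self.label(self.resolve(n)) for n in nodes]
        raise ValueError(f"to must be 'label' or 'number', got {to!r}")

    def find_descendant(
        self,
        node: NodeRef,
        only_leaf: bool = False,
        self_include: bool = False,
    ) -> list[int]:
        """Descendant node numbers of ``node``, in ascending order."""
        num = self.resolve(node)
        out = []
        stack = list(self._children[num])
        while stack:
            v = stack.pop()
            if not only_leaf or self.is_tip(v):
                out.append(v)
            stack.extend(self._children[v])
        if self_include and (not only_leaf or self.is_tip(num)):
            out.append(num)
        return sorted(out)

    def find_child(self, node: NodeRef) -> list[int]:
        """Direct children, in stored order."""
        return list(self._children[self.resolve(node)])

    def find_ancestor(self, node: NodeRef, level: int = 1) -> int:
        """Walk ``level`` edges rootward; error if that passes the root."""
        if level < 1:
            raise ValueError("level must be a positive integer")
        num = self.resolve(node)
        for _ in range(level):
            if num not in self._parent:
                raise ValidationError(
                    f"ancestor level {level} of node {node!r} is above the root"
                )
            num = self._parent[num]
        return num

    def find_sibling(self, node: NodeRef) -> list[int]:
        """The parent's other children; empty for the root."""
        num = self.resolve(node)
        p = self._parent.get(num)
        if p is None:
            return []
        return [c for c in self._children[p] if c != num]

    def _root_path(self, num: int) -> list[int]:
        path = [num]
        while num in self._parent:
            num = self._parent[num]
            path.append(num)
        return path

    def share_node(self, nodes: Sequence[NodeRef]) -> int:
        """First node shared by the root-paths of ``nodes`` (their LCA)."""
        if not nodes:
            raise ValueError("share_node requires a non-empty list of nodes")
        nums = [self.resolve(n) for n in nodes]
        common = set(self._root_path(nums[0]))
        for num in nums[1:]:
            common &= set(self._root_path(num))
        # the first common node along any member's root-path is the deepest
        for v in self._root_path(nums[0]):
            if v in common:
                return v
        raise AssertionError("unreachable: root is always shared")

    def union_leaf(self, nodes: Sequence[NodeRef]) -> list[int]:
        """Ascending duplicate-free union of descendant-or-self tips."""
        out: set[int] = set()
        for n in nodes:
            out.update(
                self.find_descendant(n, only_leaf=True, self_include=True)
            )
        return sorted(out)

    def join_node(self, nodes: Sequence[NodeRef]) -> list[int]:
        """Represent the node set minimally by replacing complete sibling
        sets with their parent, to a fixed point.  Preserves the union of
        descendant leaves exactly."""
        s = {self.resolve(n) for n in nodes}
        changed = True
        while changed:
            changed = False
            for v in range(self.n_tips + 1, self.n_nodes + 1):
                ch = self._children[v]
                if ch and v not in s and set(ch) <= s:
                    s.difference_update(ch)
                    s.add(v)
                    changed = True
        return sorted(s)

    def dist_node(self, a: NodeRef, b: NodeRef) -> float:
        """Sum of branch lengths on the unique a-b path (1 per edge where
        lengths are absent)."""
        na, nb = self.resolve(a), self.resolve(b)
        anc = self.share_node([na, nb])
        d = 0.0
        for num in (na, nb):
            while num != anc:
                d += self.edge_length(num)
                num = self._parent[num]
        return d

    def mat_tree(self) -> pd.DataFrame:
        """One row per tip: node numbers from the tip to the root, padded
        with missing values to equal length."""
        paths = [self._root_path(t) for t in range(1, self.n_tips + 1)]
        width = max(len(p) for p in paths)
        rows = [p + [pd.NA] * (width - len(p)) for p in paths]
        return pd.DataFrame(
            rows, columns=[f"L{i + 1}" for i in range(width)], dtype="Int64"
        )

    def is_leaf(self, nodes) -> Union[bool, list[bool]]:
        """Leaf flags for one node reference or a list of them."""
        if isinstance(nodes, (list, tuple)):
            return [self.is_tip(self.resolve(n)) for n in nodes]
        return self.is_tip(self.resolve(nodes))

    def count_node(self) -> int:
        """Total number of nodes (tips plus internals)."""
        return self.n_nodes

    def show_node(self, only_leaf: bool = False) -> list[int]:
        """All node numbers (or only tips), ascending."""
        if only_leaf:
            return list(range(1, self.n_tips + 1))
        return list(range(1, self.n_nodes + 1))

    def print_node(self, type: str = "all") -> pd.DataFrame:
        """Table of (nodeLab, nodeNum, isLeaf) for the requested node class."""
        if type not in ("leaf", "internal", "all"):
            raise ValueError("type must be one of 'leaf', 'internal', 'all'")
        nums = self.show_node()
        if type == "leaf":
            nums = [v for v in nums if self.is_tip(v)]
        elif type == "internal":
            nums = [v for v in nums if not self.is_tip(v)]
        return pd.DataFrame(
            {
                "nodeLab": [self.label(v) for v in nums],
                "nodeNum": nums,
                "isLeaf": [self.is_tip(v) for v in nums],
            }
        )

    # ------------------------------------------------------------------
    # tree-producing operations
    # ------------------------------------------------------------------

    def _copy_nodes(self) -> tuple[_N, dict[int, _N]]:
        """Deep copy into construction nodes; also return number -> node."""
        by_num: dict[int, _N] = {}

        def build(num: int) -> _N:
            n = _N(
                label=self.label(num) or None,
                length=None
                if self.branch_lengths is None or num == self.root
                else self.branch_lengths.get(num),
                children=[build(c) for c in self._children[num]],
            )
            by_num[num] = n
            return n

        return build(self.root), by_num

    def add_label(self, on: str = "internal", fmt: str = "Node_{number}") -> "Tree":
        """Label unlabeled nodes in scope with ``fmt`` applied to their
        current number; existing labels are untouched."""
        if on not in ("internal", "leaf", "all"):
            raise ValueError("on must be one of 'internal', 'leaf', 'all'")
        root, by_num = self._copy_nodes()
        for num, n in by_num.items():
            tip = self.is_tip(num)
            in_scope = on == "all" or (on == "leaf") == tip
            if in_scope and not n.label:
                n.label = fmt.format(number=num)
        return Tree(root)

    def track_node(self) -> "Tree":
        """Relabel every node ``alias_{number}`` under the current numbering,
        so node identity survives pruning and renumbering."""
        root, by_num = self._copy_nodes()
        for num, n in by_num.items():
            n.label = f"alias_{num}"
        return Tree(root)

    def keep_tips(self, tips: Sequence[NodeRef]) -> "Tree":
        """Prune the tree to the given tips.

        Internal nodes left with a single child are suppressed and their
        branch lengths summed; numbering is recomputed canonically.
        """
        if not tips:
            raise ValidationError("keep_tips requires at least one tip")
        keep: set[int] = set()
        for t in tips:
            num = self.resolve(t)
            if not self.is_tip(num):
                raise ValidationError(
                    f"keep_tips: node {t!r} is not a tip of this tree"
                )
            keep.add(num)
        root, by_num = self._copy_nodes()

        def prune(num: int) -> Optional[_N]:
            n = by_num[num]
            if self.is_tip(num):
                return n if num in keep else None
            kept = [prune(c) for c in self._children[num]]
            n.children = [c for c in kept if c is not None]
            return n if n.children else None

        new_root = prune(self.root)
        assert new_root is not None

        def suppress(n: _N) -> _N:
            while len(n.children) == 1:
                child = n.children[0]
                if n.length is None and child.length is None:
                    pass
                else:
                    child.length = (n.length or 0.0) + (child.length or 0.0)
                n = child
            n.children = [suppress(c) for c in n.children]
            return n

        new_root = suppress(new_root)
        new_root.length = None
        return Tree(new_root)

    def as_leaf(self, nodes: Sequence[NodeRef]) -> "Tree":
        """Collapse each given internal node into a tip that retains its
        label; the nodes must not be ancestors of one another."""
        nums = [self.resolve(n) for n in nodes]
        if not nums:
            return Tree(self._copy_nodes()[0])
        for v in nums:
            if self.is_tip(v):
                raise ValidationError(f"as_leaf: node {v} is already a leaf")
            if self.label(v) is None:
                raise ValidationError(
                    f"as_leaf: node {v} is unlabeled and cannot become a tip; "
                    "apply add_label first"
                )
        for v in nums:
            desc = set(self.find_descendant(v))
            if desc.intersection(nums):
                raise ValidationError(
                    "as_leaf: the given nodes must not be ancestors of one "
                    "another"
                )
        root, by_num = self._copy_nodes()
        for v in nums:
            by_num[v].children = []
        return Tree(root)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return parse_newick(text)


def _scan_newick(text: str) -> None:
    """Cheap structural pre-check giving character offsets for the common
    malformations before handing off to the full parser."""
    depth = 0
    in_quote = False
    for i, c in enumerate(text):
        if in_quote:
            if c == "'":
                in_quote = False
            continue
        if c == "'":
            in_quote = True
        elif c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if in_quote:
        raise NewickParseError("unterminated quoted label", offset=len(text))
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '('", offset=len(text))
    if ";" not in text:
        raise NewickParseError("missing terminating ';'", offset=len(text))


def parse_newick(text: str) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    Canonical node numbering is recomputed on parse; duplicate labels raise
    a :class:`ValidationError` and malformed input a
    :class:`NewickParseError` with a character offset where known.
    """
    _scan_newick(text)
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            # label uniqueness is validated by Tree itself, with a uniform
            # error, so labels are not parsed as taxon concepts
            suppress_leaf_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {e}") from None

    def conv(nd) -> _N:
        label = nd.taxon.label if nd.taxon is not None else nd.label
        return _N(
            label=label or None,
            length=nd.edge.length,
            children=[conv(c) for c in nd.child_nodes()],
        )

    return Tree(conv(dt.seed_node))


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` to Newick, preserving stored child order,
    labels, and branch lengths to 12 significant digits."""
    buf = io.StringIO()

    def w(num: int) -> None:
        ch = tree._children[num]
        if ch:
            buf.write("(")
            for i, c in enumerate(ch):
                if i:
                    buf.write(",")
                w(c)
            buf.write(")")
            lab = tree.label(num)
            if lab:
                buf.write(_quote_label(lab))
        else:
            buf.write(_quote_label(tree.label(num)))
        if (
            tree.branch_lengths is not None
            and num != tree.root
            and num in tree.branch_lengths
        ):
            buf.write(":" + _fmt_len(tree.branch_lengths[num]))

    w(tree.root)
    buf.write(";")
    return buf.getvalue()
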