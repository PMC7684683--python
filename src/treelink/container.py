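"""The tree-linked experiment container.

:class:`TreeExperiment` stores named assay matrices (features x samples)
together with row/column annotation tables and, optionally, a rooted tree
on either dimension.  When a tree is attached, a *link table* records for
every row (column) the tree node it maps to: its label, a synthetic alias
``alias_{number}``, its number, a leaf flag and the tree identifier.  Links
are generated automatically at construction, maintained through subsetting,
and rebuilt when a tree is replaced.

Several rows may link to the same node; rows whose label cannot be matched
to any node label of the tree are dropped with a warning, since the tree
takes precedence in deciding which entities the container keeps.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .tree import NodeRef, Tree

__all__ = ["TreeExperiment", "build", "LINK_COLUMNS"]

LINK_COLUMNS = ["nodeLab", "nodeLab_alias", "nodeNum", "isLeaf", "whichTree"]

#: single-tree container: every link carries this constant tree id
WHICH_TREE = "phylo"


def _as_frame(obj, what: str) -> pd.DataFrame:
    if not isinstance(obj, pd.DataFrame):
        raise ValidationError(f"{what} must be a pandas DataFrame")
    return obj


def _make_links(tree: Tree, labels: Sequence[str], index) -> pd.DataFrame:
    nums = [tree.resolve(lab) for lab in labels]
    return pd.DataFrame(
        {
            "nodeLab": [tree.label(v) or tree.alias(v) for v in nums],
            "nodeLab_alias": [tree.alias(v) for v in nums],
            "nodeNum": nums,
            "isLeaf": [tree.is_tip(v) for v in nums],
            "whichTree": WHICH_TREE,
        },
        index=index,
    )


def _match(
    tree: Tree,
    labels: Sequence[str],
    dim_name: str,
) -> list[int]:
    """Positions whose label occurs among the tree's node labels; warns
    about the rest in the style '<n> row(s) couldn't be matched ...'."""
    known = tree.labels()
    kept = [i for i, lab in enumerate(labels) if lab in known]
    dropped = len(labels) - len(kept)
    if dropped:
        warnings.warn(
            f"{dropped} {dim_name}(s) couldn't be matched to the tree "
            "and are/is removed.",
            stacklevel=3,
        )
    if not kept:
        raise ValidationError(
            f"no {dim_name}s could be matched to the tree"
        )
    return kept


class TreeExperiment:
    """Assay matrices with optional row/column trees and link tables.

    Parameters
    ----------
    assays :
        Mapping of assay name to DataFrame.  All assays must share their
        index (row names) and columns (column names).
    row_data, col_data :
        Annotation tables aligned to the assay dimensions (optional).
    row_tree, col_tree :
        Optional :class:`~treelink.tree.Tree` on either dimension.
    row_node_labels, col_node_labels :
        Node labels used to match the dimension to the tree; defaults to
        the dimension names.  Unmatched entries are dropped with a warning.
    reference_seqs :
        Optional list of Biopython ``SeqRecord`` objects, one per row.
    """

    def __init__(
        self,
        assays: dict[str, pd.DataFrame],
        row_data: Optional[pd.DataFrame] = None,
        col_data: Optional[pd.DataFrame] = None,
        row_tree: Optional[Tree] = None,
        col_tree: Optional[Tree] = None,
        row_node_labels: Optional[Sequence[str]] = None,
        col_node_labels: Optional[Sequence[str]] = None,
        reference_seqs=None,
        metadata: Optional[dict] = None,
    ):
        if not assays:
            raise ValidationError("at least one assay is required")
        assays = {str(k): _as_frame(v, f"assay {k!r}") for k, v in assays.items()}
        first = next(iter(assays.values()))
        for name, a in assays.items():
            if a.shape != first.shape or list(a.index) != list(first.index) or \
                    list(a.columns) != list(first.columns):
                raise ValidationError(
                    f"assay {name!r} does not share the dimensions of the "
                    "first assay"
                )
        row_names = list(map(str, first.index))
        col_names = list(map(str, first.columns))

        if row_data is None:
            row_data = pd.DataFrame(index=first.index)
        if col_data is None:
            col_data = pd.DataFrame(index=first.columns)
        _as_frame(row_data, "row_data")
        _as_frame(col_data, "col_data")
        if len(row_data) != len(row_names):
            raise ValidationError("row_data length does not match assay rows")
        if len(col_data) != len(col_names):
            raise ValidationError("col_data length does not match assay columns")

        if reference_seqs is not None and len(reference_seqs) != len(row_names):
            raise ValidationError(
                f"reference_seqs has {len(reference_seqs)} sequences for "
                f"{len(row_names)} rows"
            )

        row_keep, row_links = self._link_dim(
            row_tree, row_node_labels, row_names, "row"
        )
        col_keep, col_links = self._link_dim(
            col_tree, col_node_labels, col_names, "column"
        )

        if row_keep is not None:
            assays = {k: a.iloc[row_keep] for k, a in assays.items()}
            row_data = row_data.iloc[row_keep]
            if reference_seqs is not None:
                reference_seqs = [reference_seqs[i] for i in row_keep]
        if col_keep is not None:
            assays = {k: a.iloc[:, col_keep] for k, a in assays.items()}
            col_data = col_data.iloc[col_keep]

        self._assays = assays
        self._row_data = row_data
        self._col_data = col_data
        self._row_tree = row_tree
        self._col_tree = col_tree
        self._row_links = row_links
        self._col_links = col_links
        self._reference_seqs = list(reference_seqs) if reference_seqs is not None else None
        self.metadata = dict(metadata) if metadata else {}
        self._validate()

    @staticmethod
    def _link_dim(tree, node_labels, dim_names, dim):
        if tree is None:
            if node_labels is not None:
                raise ValidationError(
                    f"{dim} node labels given without a {dim} tree"
                )
            return None, None
        labels = list(map(str, node_labels)) if node_labels is not None else dim_names
        if len(labels) != len(dim_names):
            raise ValidationError(
                f"{dim} node-label vector has length {len(labels)}, "
                f"expected {len(dim_names)}"
            )
        keep = _match(tree, labels, dim)
        links = _make_links(
            tree,
            [labels[i] for i in keep],
            [dim_names[i] for i in keep],
        )
        return keep, links

    @classmethod
    def _assemble(
        cls,
        assays,
        row_data,
        col_data,
        row_tree,
        col_tree,
        row_links,
        col_links,
        reference_seqs,
        metadata,
    ) -> "TreeExperiment":
        """Internal constructor from already-consistent parts."""
        x = cls.__new__(cls)
        x._assays = assays
        x._row_data = row_data
        x._col_data = col_data
        x._row_tree = row_tree
        x._col_tree = col_tree
        x._row_links = row_links
        x._col_links = col_links
        x._reference_seqs = reference_seqs
        x.metadata = dict(metadata) if metadata else {}
        x._validate()
        return x

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------

    def _validate(self) -> None:
        for dim, tree, links, n in (
            ("row", self._row_tree, self._row_links, self.n_rows),
            ("col", self._col_tree, self._col_links, self.n_cols),
        ):
            if (tree is None) != (links is None):
                raise ValidationError(
                    f"{dim}_links must be present iff {dim}_tree is present"
                )
            if links is None:
                continue
            if list(links.columns) != LINK_COLUMNS:
                raise ValidationError(f"{dim}_links has wrong columns")
            if len(links) != n:
                raise ValidationError(
                    f"{dim}_links has {len(links)} rows for dimension "
                    f"length {n}"
                )
            for lab, alias, num, leaf in zip(
                links["nodeLab"], links["nodeLab_alias"], links["nodeNum"],
                links["isLeaf"],
            ):
                num = int(num)
                tree.resolve(num)
                if alias != f"alias_{num}":
                    raise ValidationError(
                        f"{dim}_links alias {alias!r} inconsistent with "
                        f"node number {num}"
                    )
                if bool(leaf) != tree.is_tip(num):
                    raise ValidationError(
                        f"{dim}_links leaf flag inconsistent for node {num}"
                    )
                if lab != (tree.label(num) or f"alias_{num}"):
                    raise ValidationError(
                        f"{dim}_links label {lab!r} inconsistent for node "
                        f"{num}"
                    )
        if self._reference_seqs is not None and len(self._reference_seqs) != self.n_rows:
            raise ValidationError("reference_seqs length mismatch")

    # ------------------------------------------------------------------
    # accessors
    # ------------------------------------------------------------------

    @property
    def assays(self) -> dict[str, pd.DataFrame]:
        return dict(self._assays)

    @property
    def assay_names(self) -> list[str]:
        return list(self._assays)

    def assay(self, name: Optional[str] = None) -> pd.DataFrame:
        if name is None:
            return next(iter(self._assays.values()))
        return self._assays[name]

    @property
    def row_data(self) -> pd.DataFrame:
        return self._row_data

    @property
    def col_data(self) -> pd.DataFrame:
        return self._col_data

    @property
    def row_tree(self) -> Optional[Tree]:
        return self._row_tree

    @property
    def col_tree(self) -> Optional[Tree]:
        return self._col_tree

    @property
    def row_links(self) -> Optional[pd.DataFrame]:
        return self._row_links

    @property
    def col_links(self) -> Optional[pd.DataFrame]:
        return self._col_links

    @property
    def n_rows(self) -> int:
        return self.assay().shape[0]

    @property
    def n_cols(self) -> int:
        return self.assay().shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.assay().shape

    @property
    def row_names(self) -> list[str]:
        return list(map(str, self.assay().index))

    @property
    def col_names(self) -> list[str]:
        return list(map(str, self.assay().columns))

    def get_reference_seqs(self):
        return self._reference_seqs

    def set_reference_seqs(self, sequences) -> "TreeExperiment":
        """Return a copy with per-row reference sequences attached (or
        removed when ``sequences`` is None)."""
        if sequences is not None and len(sequences) != self.n_rows:
            raise ValidationError(
                f"expected {self.n_rows} sequences, got {len(sequences)}"
            )
        return self._replace(
            reference_seqs=list(sequences) if sequences is not None else None
        )

    def _replace(self, **kw) -> "TreeExperiment":
        parts = dict(
            assays=self._assays,
            row_data=self._row_data,
            col_data=self._col_data,
            row_tree=self._row_tree,
            col_tree=self._col_tree,
            row_links=self._row_links,
            col_links=self._col_links,
            reference_seqs=self._reference_seqs,
            metadata=self.metadata,
        )
        parts.update(kw)
        return TreeExperiment._assemble(**parts)

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------

    def subset_by_index(
        self,
        row_idx: Optional[Sequence[int]] = None,
        col_idx: Optional[Sequence[int]] = None,
    ) -> "TreeExperiment":
        """Subset rows/columns by integer position.

        All aligned components (assays, annotation tables, links, reference
        sequences) are subset in lockstep; trees are left untouched so node
        numbers remain valid.
        """
        def check(idx, n, dim):
            idx = [int(i) for i in idx]
            for i in idx:
                if not 0 <= i < n:
                    raise IndexError(f"{dim} index {i} out of range 0..{n - 1}")
            return idx

        assays = self._assays
        row_data, col_data = self._row_data, self._col_data
        row_links, col_links = self._row_links, self._col_links
        seqs = self._reference_seqs
        if row_idx is not None:
            row_idx = check(row_idx, self.n_rows, "row")
            assays = {k: a.iloc[row_idx] for k, a in assays.items()}
            row_data = row_data.iloc[row_idx]
            if row_links is not None:
                row_links = row_links.iloc[row_idx]
            if seqs is not None:
                seqs = [seqs[i] for i in row_idx]
        if col_idx is not None:
            col_idx = check(col_idx, self.n_cols, "column")
            assays = {k: a.iloc[:, col_idx] for k, a in assays.items()}
            col_data = col_data.iloc[col_idx]
            if col_links is not None:
                col_links = col_links.iloc[col_idx]
        return self._replace(
            assays=assays, row_data=row_data, col_data=col_data,
            row_links=row_links, col_links=col_links, reference_seqs=seqs,
        )

    def __getitem__(self, key) -> "TreeExperiment":
        if not isinstance(key, tuple) or len(key) != 2:
            raise TypeError("use x[row_idx, col_idx]")

        def norm(k, n):
            if isinstance(k, slice):
                return list(range(n))[k]
            if isinstance(k, int):
                return [k]
            return list(k)

        return self.subset_by_index(norm(key[0], self.n_rows),
                                    norm(key[1], self.n_cols))

    def subset_by_node(
        self,
        row_nodes: Optional[Sequence[NodeRef]] = None,
        col_nodes: Optional[Sequence[NodeRef]] = None,
    ) -> "TreeExperiment":
        """Keep exactly the rows/columns linked to the given tree nodes,
        preserving original order; trees are not pruned."""
        row_idx = col_idx = None
        if row_nodes is not None:
            if self._row_tree is None:
                raise ValidationError("container has no row tree")
            want = {self._row_tree.resolve(n) for n in row_nodes}
            nums = self._row_links["nodeNum"]
            row_idx = [i for i, v in enumerate(nums) if int(v) in want]
        if col_nodes is not None:
            if self._col_tree is None:
                raise ValidationError("container has no column tree")
            want = {self._col_tree.resolve(n) for n in col_nodes}
            nums = self._col_links["nodeNum"]
            col_idx = [i for i, v in enumerate(nums) if int(v) in want]
        return self.subset_by_index(row_idx, col_idx)

    # ------------------------------------------------------------------
    # tree replacement
    # ------------------------------------------------------------------

    def change_tree(
        self,
        row_tree: Optional[Tree] = None,
        row_node_labels: Optional[Sequence[str]] = None,
        col_tree: Optional[Tree] = None,
        col_node_labels: Optional[Sequence[str]] = None,
    ) -> "TreeExperiment":
        """Replace the row and/or column tree.

        Entries are matched to the new tree by the provided node labels,
        falling back to the current link labels (or the dimension names
        when no tree was attached).  Unmatched entries are dropped with a
        warning; links are rebuilt against the new tree.
        """
        x = self
        if row_tree is not None:
            x = x._change_one(row_tree, row_node_labels, axis=0)
        if col_tree is not None:
            x = x._change_one(col_tree, col_node_labels, axis=1)
        return x

    def _change_one(self, tree, node_labels, axis) -> "TreeExperiment":
        dim = "row" if axis == 0 else "column"
        n = self.n_rows if axis == 0 else self.n_cols
        links = self._row_links if axis == 0 else self._col_links
        names = self.row_names if axis == 0 else self.col_names
        if node_labels is not None:
            labels = list(map(str, node_labels))
            if len(labels) != n:
                raise ValidationError(
                    f"{dim} node-label vector has length {len(labels)}, "
                    f"expected {n}"
                )
        elif links is not None:
            labels = list(links["nodeLab"])
        else:
            labels = names
        keep = _match(tree, labels, dim)
        new_links = _make_links(
            tree, [labels[i] for i in keep], [names[i] for i in keep]
        )
        sub = self.subset_by_index(
            row_idx=keep if axis == 0 else None,
            col_idx=keep if axis == 1 else None,
        )
        if axis == 0:
            return sub._replace(row_tree=tree, row_links=new_links)
        return sub._replace(col_tree=tree, col_links=new_links)

    def set_row_tree(
        self, tree: Optional[Tree], node_labels: Optional[Sequence[str]] = None
    ) -> "TreeExperiment":
        """Attach, replace or (with None) remove the row tree; links are
        updated automatically."""
        if tree is None:
            return self._replace(row_tree=None, row_links=None)
        return self.change_tree(row_tree=tree, row_node_labels=node_labels)

    def set_col_tree(
        self, tree: Optional[Tree], node_labels: Optional[Sequence[str]] = None
    ) -> "TreeExperiment":
        if tree is None:
            return self._replace(col_tree=None, col_links=None)
        return self.change_tree(col_tree=tree, col_node_labels=node_labels)

    # ------------------------------------------------------------------
    # leaf subsetting with pruning
    # ------------------------------------------------------------------

    def subset_by_leaf(self, row_leaves: Sequence[NodeRef]) -> "TreeExperiment":
        """Keep the rows linked to the given leaves and prune the row tree
        to exactly those leaves.

        Node identity across the renumbering caused by pruning is kept via
        alias tracking: the tree is relabeled ``alias_{number}``, pruned,
        and each retained row's old alias is looked up in the pruned tree
        to rebuild its link.
        """
        if self._row_tree is None:
            raise ValidationError("container has no row tree")
        old = self._row_tree
        leaf_nums = [old.resolve(l) for l in row_leaves]
        for v in leaf_nums:
            if not old.is_tip(v):
                raise ValidationError(
                    f"subset_by_leaf: node {v} is not a leaf of the row tree"
                )
        sub = self.subset_by_node(row_nodes=leaf_nums)
        if sub.n_rows == 0:
            raise ValidationError(
                "no rows are linked to any of the requested leaves"
            )
        new_tree = old.keep_tips(leaf_nums)
        track = old.track_node().keep_tips(leaf_nums)
        old_alias = list(sub.row_links["nodeLab_alias"])
        new_nums = track.convert_node(old_alias, to="number")
        new_labels = new_tree.convert_node(new_nums, to="label")
        return sub.change_tree(row_tree=new_tree, row_node_labels=new_labels)

    # ------------------------------------------------------------------
    # aggregation (delegates to treelink.aggregate)
    # ------------------------------------------------------------------

    def aggregate(self, spec=None, **kwargs) -> "TreeExperiment":
        from .aggregate import aggregate

        return aggregate(self, spec=spec, **kwargs)

    # ------------------------------------------------------------------
    # display
    # ------------------------------------------------------------------

    def render_summary(self) -> str:
        """Multi-line summary in the style of assay-container printouts."""
        def names_line(what, names):
            if len(names) > 4:
                shown = f"{names[0]} {names[1]} ... {names[-2]} {names[-1]}"
            else:
                shown = " ".join(names)
            return f"{what}({len(names)}): {shown}"

        lines = [
            "class: TreeExperiment",
            f"dim: {self.n_rows} {self.n_cols}",
            f"metadata({len(self.metadata)}): "
            + " ".join(self.metadata),
            names_line("assays", self.assay_names),
            names_line("rownames", self.row_names),
            names_line("rowData names", list(map(str, self._row_data.columns))),
            names_line("colnames", self.col_names),
            names_line("colData names", list(map(str, self._col_data.columns))),
        ]
        for dim, links, tree in (
            ("row", self._row_links, self._row_tree),
            ("col", self._col_links, self._col_tree),
        ):
            if tree is None:
                lines.append(f"{dim}Links: NULL")
                lines.append(f"{dim}Tree: NULL")
            else:
                lines.append(
                    f"{dim}Links: a LinkDataFrame ({len(links)} rows)"
                )
                lines.append(
                    f"{dim}Tree: 1 phylo tree(s) ({tree.n_tips} leaves)"
                )
        n_seq = (
            "NULL" if self._reference_seqs is None
            else f"{len(self._reference_seqs)} sequence(s)"
        )
        lines.append(f"referenceSeq: {n_seq}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return self.render_summary()


def build(
    assays,
    row_table: Optional[pd.DataFrame] = None,
    col_table: Optional[pd.DataFrame] = None,
    row_tree: Optional[Tree] = None,
    col_tree: Optional[Tree] = None,
    row_node_labels: Optional[Sequence[str]] = None,
    col_node_labels: Optional[Sequence[str]] = None,
    reference_seqs=None,
    metadata: Optional[dict] = None,
) -> TreeExperiment:
    """Construct a :class:`TreeExperiment`; see the class docstring."""
    return TreeExperiment(
        assays,
        row_data=row_table,
        col_data=col_table,
        row_tree=row_tree,
        col_tree=col_tree,
        row_node_labels=row_node_labels,
        col_node_labels=col_node_labels,
        reference_seqs=reference_seqs,
        metadata=metadata,
    )
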