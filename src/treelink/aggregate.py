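"""Aggregation of assay data to arbitrary tree node sets.

Each requested *target* node becomes one output row (or column) that
summarizes its contributors: the entries whose linked node lies in the
target's descendant-or-self set.  The reducer is applied independently per
opposing-dimension position, so e.g. summing counts to a phylum node adds
up, per sample, the counts of every OTU row under that phylum.  Overlapping
targets are allowed — an entry may contribute to several output rows — and
targets need not cover all entries.

Annotation tables collapse per column: contributors that agree keep the
shared value, disagreement yields a missing value.  With a row *block*
column set, reduction is additionally restricted within each block value
(e.g. per sample id), producing one output row per (target, block) pair.
"""

from __future__ import annotations

import logging
import statistics
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .container import WHICH_TREE, TreeExperiment
from .errors import TreelinkError, ValidationError
from .tree import NodeRef, Tree

__all__ = [
    "AggregationSpec",
    "aggregate",
    "collapse_metadata",
    "resolve_level",
    "REDUCERS",
]

logger = logging.getLogger(__name__)

#: reducers selectable by name (CLI and bundle manifests)
REDUCERS: dict[str, Callable] = {
    "sum": sum,
    "mean": statistics.fmean,
    "median": statistics.median,
    "min": min,
    "max": max,
    "count": len,
}


@dataclass
class AggregationSpec:
    """Aggregation request; at least one of row_level/col_level required."""

    row_level: Optional[Sequence[NodeRef]] = None
    col_level: Optional[Sequence[NodeRef]] = None
    row_reducer: Callable = sum
    col_reducer: Callable = sum
    row_first: bool = True
    row_block: Optional[str] = None
    which_assays: Optional[Sequence[str]] = None
    message: bool = False

    def __post_init__(self):
        if self.row_level is None and self.col_level is None:
            raise ValidationError(
                "at least one of row_level / col_level must be given"
            )
        if isinstance(self.row_reducer, str):
            self.row_reducer = REDUCERS[self.row_reducer]
        if isinstance(self.col_reducer, str):
            self.col_reducer = REDUCERS[self.col_reducer]


def resolve_level(tree: Tree, level: Sequence[NodeRef]) -> list[int]:
    """Resolve a mixed list of labels/numbers to node numbers, preserving
    input order and dropping duplicates."""
    out: list[int] = []
    seen: set[int] = set()
    for ref in level:
        num = tree.resolve(ref)
        if num not in seen:
            seen.add(num)
            out.append(num)
    return out


def collapse_metadata(table: pd.DataFrame, groups) -> pd.DataFrame:
    """Collapse an annotation table over contributor groups.

    ``groups`` is a sequence of ``(name, positions)`` pairs.  Per group and
    per column the shared value is kept when all contributors agree,
    otherwise the entry becomes missing; column dtypes are preserved where
    the collapsed values allow it.
    """
    names = [name for name, _ in groups]
    data: dict = {}
    for col in table.columns:
        series = table[col]
        vals = []
        for _, pos in groups:
            sub = series.iloc[list(pos)]
            uniq = sub.unique()
            if len(uniq) == 1 and len(sub) > 0:
                vals.append(uniq[0])
            else:
                vals.append(pd.NA)
        data[col] = vals
    out = pd.DataFrame(data, index=names, columns=table.columns)
    for col in table.columns:
        try:
            out[col] = out[col].astype(table[col].dtype)
        except (TypeError, ValueError):
            if pd.api.types.is_integer_dtype(table[col].dtype):
                # integer column with introduced missing values
                out[col] = out[col].astype("Int64")
    return out


def _descendant_or_self(tree: Tree, num: int) -> set[int]:
    return set(tree.find_descendant(num, only_leaf=False, self_include=True))


def _agg_axis(
    x: TreeExperiment,
    axis: int,
    level: Sequence[NodeRef],
    reducer: Callable,
    block: Optional[str],
    message: bool,
) -> TreeExperiment:
    dim = "row" if axis == 0 else "column"
    tree = x.row_tree if axis == 0 else x.col_tree
    links = x.row_links if axis == 0 else x.col_links
    table = x.row_data if axis == 0 else x.col_data
    if tree is None:
        raise ValidationError(f"container has no {dim} tree to aggregate over")
    targets = resolve_level(tree, level)
    linked = [int(v) for v in links["nodeNum"]]

    if block is not None:
        if block not in table.columns:
            raise ValidationError(
                f"block column {block!r} not found in {dim} annotation table"
            )
        block_vals = list(table[block])

    # output groups: (name, target node, block value or None, positions)
    group_rows: list[tuple[str, int, object, list[int]]] = []
    for v in targets:
        scope = _descendant_or_self(tree, v)
        pos = [i for i, num in enumerate(linked) if num in scope]
        if message:
            logger.info("aggregating %s node %s: %d contributor(s)",
                        dim, v, len(pos))
        if not pos:
            warnings.warn(
                f"{dim} aggregation target node {v} has no contributors; "
                "filling with missing values",
                stacklevel=3,
            )
            group_rows.append((tree.alias(v), v, None, []))
            continue
        if block is None:
            group_rows.append((tree.alias(v), v, None, pos))
        else:
            order: list = []
            by_block: dict = {}
            for i in pos:
                b = block_vals[i]
                if b not in by_block:
                    by_block[b] = []
                    order.append(b)
                by_block[b].append(i)
            for b in order:
                group_rows.append(
                    (f"{tree.alias(v)}.{b}", v, b, by_block[b])
                )

    names = [name for name, *_ in group_rows]

    def reduce_frame(a: pd.DataFrame) -> pd.DataFrame:
        mat = a.to_numpy() if axis == 0 else a.to_numpy().T
        out = np.full((len(group_rows), mat.shape[1]), np.nan, dtype=float)
        for r, (_, v, _, pos) in enumerate(group_rows):
            if not pos:
                continue
            for j in range(mat.shape[1]):
                try:
                    out[r, j] = reducer(list(mat[pos, j]))
                except Exception as e:
                    raise TreelinkError(
                        f"reducer failed on {dim} target node {v}: {e}"
                    ) from e
        if axis == 0:
            return pd.DataFrame(out, index=names, columns=a.columns)
        return pd.DataFrame(out.T, index=a.index, columns=names)

    new_assays = {k: reduce_frame(a) for k, a in x.assays.items()}

    groups = [(name, pos) for name, _, _, pos in group_rows]
    new_table = collapse_metadata(table, groups)
    if block is not None:
        new_table[block] = [b for _, _, b, _ in group_rows]

    new_links = pd.DataFrame(
        {
            "nodeLab": [tree.label(v) or tree.alias(v) for _, v, _, _ in group_rows],
            "nodeLab_alias": [tree.alias(v) for _, v, _, _ in group_rows],
            "nodeNum": [v for _, v, _, _ in group_rows],
            "isLeaf": [tree.is_tip(v) for _, v, _, _ in group_rows],
            "whichTree": WHICH_TREE,
        },
        index=names,
    )

    if axis == 0:
        return TreeExperiment._assemble(
            assays=new_assays, row_data=new_table, col_data=x.col_data,
            row_tree=tree, col_tree=x.col_tree,
            row_links=new_links, col_links=x.col_links,
            reference_seqs=None, metadata=x.metadata,
        )
    return TreeExperiment._assemble(
        assays=new_assays, row_data=x.row_data, col_data=new_table,
        row_tree=x.row_tree, col_tree=tree,
        row_links=x.row_links, col_links=new_links,
        reference_seqs=x.get_reference_seqs(), metadata=x.metadata,
    )


def aggregate(
    x: TreeExperiment,
    spec: Optional[AggregationSpec] = None,
    **kwargs,
) -> TreeExperiment:
    """Aggregate a container per an :class:`AggregationSpec` (or keyword
    arguments building one); returns a new container whose aggregated
    dimension(s) are named by the target alias labels and whose links are
    rebuilt to point at the target nodes."""
    if spec is None:
        spec = AggregationSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a spec or keyword arguments, not both")

    if spec.which_assays is not None:
        unknown = set(spec.which_assays) - set(x.assay_names)
        if unknown:
            raise ValidationError(f"unknown assay name(s): {sorted(unknown)}")
        x = x._replace(assays={k: x.assays[k] for k in spec.which_assays})

    steps = []
    if spec.row_level is not None:
        steps.append((0, spec.row_level, spec.row_reducer, spec.row_block))
    if spec.col_level is not None:
        steps.append((1, spec.col_level, spec.col_reducer, None))
    if not spec.row_first:
        steps.reverse()
    for axis, level, reducer, block in steps:
        x = _agg_axis(x, axis, level, reducer, block, spec.message)
    return x
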