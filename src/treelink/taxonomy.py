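"""Taxonomy tables and their conversion to trees.

A taxonomy table has one ordered rank column per taxonomic level
(broad -> fine, e.g. Kingdom, Phylum, Class, OTU) and one row per entity.
Before such a table can be turned into a tree, polyphyletic *loops* —
a child value appearing under two or more distinct parent values, which
would force the same node to have two parents — must be detected
(:func:`detect_loop`) and resolved by suffixing (:func:`resolve_loop`).

Absent cells are supported: a run of absent values below a named rank is
bridged, so the entity attaches to its deepest named ancestor.  For loop
analysis an absent value counts as a distinct value in its column.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .errors import ValidationError
from .tree import Tree, _N

__all__ = ["detect_loop", "resolve_loop", "to_tree"]

#: sentinel used for absent cells in loop reports / resolved values
_NA = None


def _cell(v) -> Optional[str]:
    """Normalize a table cell: absent (None/NaN/empty) -> None, else str."""
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    if pd.isna(v):
        return None
    s = str(v)
    return s if s != "" else None


def _columns(table: pd.DataFrame) -> list[str]:
    if table.shape[1] < 1:
        raise ValidationError("taxonomy table needs at least one rank column")
    return list(table.columns)


def detect_loop(table: pd.DataFrame) -> pd.DataFrame:
    """Report polyphyletic loops in a taxonomy table.

    For every adjacent rank pair, a child value that appears under two or
    more distinct parent values (absent counting as a distinct value) is
    reported with one row per (parent, child) combination.  The report has
    columns ``parent``, ``child``, ``parent_column``, ``child_column``; it
    is empty iff :func:`to_tree` can succeed without resolution.
    """
    cols = _columns(table)
    rows = []
    for pc, cc in zip(cols, cols[1:]):
        pairs: dict[Optional[str], list[Optional[str]]] = {}
        for p, c in zip(table[pc], table[cc]):
            p, c = _cell(p), _cell(c)
            parents = pairs.setdefault(c, [])
            if p not in parents:
                parents.append(p)
        for c, parents in pairs.items():
            if len(parents) > 1:
                for p in parents:
                    rows.append(
                        {
                            "parent": p,
                            "child": c,
                            "parent_column": pc,
                            "child_column": cc,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["parent", "child", "parent_column", "child_column"]
    )


def resolve_loop(table: pd.DataFrame) -> pd.DataFrame:
    """Suffix polyphyletic child values so that no loops remain.

    Each looping child value gets the suffix ``_{k}`` with ``k = 1..m``
    numbering its distinct parent values in order of first appearance, so
    e.g. a genus under two families becomes ``Genus_1`` and ``Genus_2``.
    An absent looping cell is materialized as ``NA_{k}`` so the resulting
    table is loop-free under :func:`detect_loop`.  Non-looping cells are
    unchanged and the operation is idempotent.
    """
    cols = _columns(table)
    out = table.copy()
    # broad -> fine: resolving a rank can only surface loops at finer
    # ranks, which later pairs then see through the updated parent values
    for pc, cc in zip(cols, cols[1:]):
        parents_of: dict[Optional[str], list[Optional[str]]] = {}
        for p, c in zip(out[pc], out[cc]):
            p, c = _cell(p), _cell(c)
            parents = parents_of.setdefault(c, [])
            if p not in parents:
                parents.append(p)
        looping = {c for c, ps in parents_of.items() if len(ps) > 1}
        if not looping:
            continue
        new_child = []
        for p, c in zip(out[pc], out[cc]):
            p, c = _cell(p), _cell(c)
            if c in looping:
                k = parents_of[c].index(p) + 1
                new_child.append(f"{c if c is not None else 'NA'}_{k}")
            else:
                new_child.append(c)
        out[cc] = new_child
    return out


def to_tree(table: pd.DataFrame) -> Tree:
    """Convert a loop-free taxonomy table into a :class:`Tree`.

    Leaves carry the (unprefixed) finest named value of each row; internal
    nodes are labeled ``{rank}:{value}``.  Rows with identical rank paths
    collapse into one leaf.  A single top-level value becomes the root;
    multiple top-level values are joined under a synthetic root labeled
    ``ALL``.  All branch lengths are 1.
    """
    loops = detect_loop(table)
    if len(loops):
        offending = sorted({str(c) for c in loops["child"]})
        raise ValidationError(
            f"taxonomy table contains polyphyletic loops (children: "
            f"{offending}); apply resolve_loop first"
        )
    cols = _columns(table)

    paths: list[tuple[tuple[str, str], ...]] = []
    seen: set[tuple] = set()
    for _, row in table.iterrows():
        path = tuple(
            (rank, _cell(row[rank])) for rank in cols if _cell(row[rank]) is not None
        )
        if not path:
            raise ValidationError(
                "taxonomy table has a row with no named rank values"
            )
        if path in seen:
            continue
        seen.add(path)
        paths.append(path)

    leaf_values = [p[-1][1] for p in paths]
    if len(set(leaf_values)) != len(leaf_values):
        dupes = sorted({v for v in leaf_values if leaf_values.count(v) > 1})
        raise ValidationError(
            f"duplicate leaf labels after path de-duplication: {dupes}"
        )

    synthetic_root = _N(label="ALL", length=None)
    index: dict[tuple, _N] = {(): synthetic_root}
    for path in paths:
        for i in range(len(path)):
            key = path[: i + 1]
            if key in index:
                continue
            rank, value = path[i]
            is_leaf = i == len(path) - 1
            node = _N(
                label=value if is_leaf else f"{rank}:{value}",
                length=1.0,
            )
            index[path[:i]].children.append(node)
            index[key] = node

    top = synthetic_root.children
    if len(top) == 1:
        root = top[0]
        root.length = None
    else:
        root = synthetic_root
    return Tree(root)
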