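"""On-disk serialization of containers as plain-text directory bundles.

A *bundle* is a directory holding the container's parts in standard text
formats — delimited tables for assays/annotations/links, Newick for trees,
FASTA for reference sequences — tied together by a ``manifest.yaml``.
Numbers are written with up to 12 significant digits and missing values as
``NA``, so a write/read round trip is lossless at that precision.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd
import yaml

from .container import LINK_COLUMNS, TreeExperiment
from .errors import BundleError
from .tree import Tree, parse_newick, write_newick

__all__ = ["read_bundle", "write_bundle", "read_table", "write_table",
           "read_tree", "write_tree", "read_fasta", "write_fasta"]

MANIFEST_NAME = "manifest.yaml"
NA_REP = "NA"


# ----------------------------------------------------------------------
# single-format helpers
# ----------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, na_rep=NA_REP, float_format="%.12g",
              index_label="")


def read_table(path: str, delimiter: str = "\t") -> pd.DataFrame:
    if not os.path.exists(path):
        raise BundleError(f"missing table file: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0,
                     na_values=[NA_REP], keep_default_na=False)
    df.index.name = None
    return df


def write_tree(tree: Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


def read_tree(path: str) -> Tree:
    if not os.path.exists(path):
        raise BundleError(f"missing tree file: {path}")
    with open(path) as fh:
        return parse_newick(fh.read().strip())


def write_fasta(records, path: str) -> None:
    from Bio import SeqIO

    SeqIO.write(records, path, "fasta")


def read_fasta(path: str):
    from Bio import SeqIO

    if not os.path.exists(path):
        raise BundleError(f"missing sequence file: {path}")
    return list(SeqIO.parse(path, "fasta"))


# ----------------------------------------------------------------------
# bundles
# ----------------------------------------------------------------------

def write_bundle(x: TreeExperiment, directory: str,
                 delimiter: str = "\t") -> dict:
    """Write a container to ``directory`` and return the manifest dict."""
    os.makedirs(directory, exist_ok=True)
    os.makedirs(os.path.join(directory, "assays"), exist_ok=True)
    manifest: dict = {
        "format": "treelink-bundle",
        "version": 1,
        "delimiter": delimiter,
        "assays": {},
    }
    for name, a in x.assays.items():
        rel = os.path.join("assays", f"{name}.tsv")
        write_table(a, os.path.join(directory, rel), delimiter)
        manifest["assays"][name] = rel
    write_table(x.row_data, os.path.join(directory, "row_data.tsv"), delimiter)
    write_table(x.col_data, os.path.join(directory, "col_data.tsv"), delimiter)
    manifest["row_data"] = "row_data.tsv"
    manifest["col_data"] = "col_data.tsv"
    for dim, tree, links in (
        ("row", x.row_tree, x.row_links),
        ("col", x.col_tree, x.col_links),
    ):
        if tree is None:
            continue
        write_tree(tree, os.path.join(directory, f"{dim}_tree.nwk"))
        write_table(links, os.path.join(directory, f"{dim}_links.tsv"),
                    delimiter)
        manifest[f"{dim}_tree"] = f"{dim}_tree.nwk"
        manifest[f"{dim}_links"] = f"{dim}_links.tsv"
    seqs = x.get_reference_seqs()
    if seqs is not None:
        write_fasta(seqs, os.path.join(directory, "reference_seqs.fasta"))
        manifest["reference_seqs"] = "reference_seqs.fasta"
    with open(os.path.join(directory, MANIFEST_NAME), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _read_links(path: str, delimiter: str) -> pd.DataFrame:
    links = read_table(path, delimiter)
    if list(links.columns) != LINK_COLUMNS:
        raise BundleError(
            f"{path}: expected link columns {LINK_COLUMNS}, "
            f"got {list(links.columns)}"
        )
    links["nodeNum"] = links["nodeNum"].astype(int)
    if links["isLeaf"].dtype == object:
        links["isLeaf"] = links["isLeaf"].map(
            {"True": True, "False": False}
        )
    links["isLeaf"] = links["isLeaf"].astype(bool)
    return links


def read_bundle(path: str) -> TreeExperiment:
    """Read a bundle directory (or the manifest file itself) back into a
    :class:`TreeExperiment`; raises :class:`BundleError` naming the file
    on missing pieces or shape inconsistencies."""
    if os.path.isdir(path):
        directory = path
        manifest_path = os.path.join(path, MANIFEST_NAME)
    else:
        directory = os.path.dirname(path) or "."
        manifest_path = path
    if not os.path.exists(manifest_path):
        raise BundleError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "assays" not in manifest:
        raise BundleError(f"{manifest_path}: not a treelink bundle manifest")
    delimiter = manifest.get("delimiter", "\t")

    assays: dict[str, pd.DataFrame] = {}
    for name, rel in manifest["assays"].items():
        assays[name] = read_table(os.path.join(directory, rel), delimiter)
    first_name, first = next(iter(assays.items()))
    for name, a in assays.items():
        if a.shape != first.shape:
            raise BundleError(
                f"{manifest['assays'][name]}: assay shape {a.shape} does "
                f"not match {manifest['assays'][first_name]} {first.shape}"
            )

    def table(key, expect_len, what):
        if key not in manifest:
            return None
        df = read_table(os.path.join(directory, manifest[key]), delimiter)
        if len(df) != expect_len:
            raise BundleError(
                f"{manifest[key]}: {what} has {len(df)} rows, expected "
                f"{expect_len}"
            )
        return df

    row_data = table("row_data", first.shape[0], "row annotation table")
    col_data = table("col_data", first.shape[1], "column annotation table")
    if row_data is None:
        row_data = pd.DataFrame(index=first.index)
    if col_data is None:
        col_data = pd.DataFrame(index=first.columns)

    trees = {}
    links = {}
    for dim, n in (("row", first.shape[0]), ("col", first.shape[1])):
        if f"{dim}_tree" in manifest:
            trees[dim] = read_tree(
                os.path.join(directory, manifest[f"{dim}_tree"])
            )
            if f"{dim}_links" not in manifest:
                raise BundleError(
                    f"bundle has {dim}_tree but no {dim}_links"
                )
            lk = _read_links(
                os.path.join(directory, manifest[f"{dim}_links"]), delimiter
            )
            if len(lk) != n:
                raise BundleError(
                    f"{manifest[f'{dim}_links']}: link table has {len(lk)} "
                    f"rows, expected {n}"
                )
            links[dim] = lk
        else:
            trees[dim] = None
            links[dim] = None

    seqs = None
    if "reference_seqs" in manifest:
        seqs = read_fasta(os.path.join(directory, manifest["reference_seqs"]))
        if len(seqs) != first.shape[0]:
            raise BundleError(
                f"{manifest['reference_seqs']}: {len(seqs)} sequences for "
                f"{first.shape[0]} rows"
            )

    return TreeExperiment._assemble(
        assays=assays, row_data=row_data, col_data=col_data,
        row_tree=trees["row"], col_tree=trees["col"],
        row_links=links["row"], col_links=links["col"],
        reference_seqs=seqs, metadata=None,
    )
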