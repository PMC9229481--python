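"""Readers and writers for the package's file formats.

FASTA (genomes and protein alignments, via Biopython), newick trees (via
dendropy, one tree per line so posterior tree samples are plain text files),
and the CSV tables for titers, traits, and signature reports. All user-facing
coordinates are 1-based; internal indices are 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_signature import GenomeRecord

__all__ = [
    "read_fasta",
    "read_alignment_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_traits",
    "write_traits",
]


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read genome records; ids up to first whitespace, sequences uppercased."""
    records = [
        GenomeRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids in {path}: {dupes}")
    return records


def read_alignment_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps ``-``); enforces equal aligned lengths."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate FASTA ids in {path}")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(
            f"ragged alignment in {path}: lengths {sorted(lengths)} — sequences must be aligned"
        )
    return records


def write_fasta(records: Sequence[GenomeRecord | tuple[str, str]], path: str | os.PathLike) -> None:
    seqrecs = []
    for rec in records:
        if isinstance(rec, GenomeRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def _validate_tree(tree: dendropy.Tree, lineno: int) -> None:
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError(
            f"tree on line {lineno} looks unrooted (root has "
            f"{len(tree.seed_node.child_nodes())} children); root it (e.g. midpoint "
            "or outgroup rooting) before use — the trait model needs a rooted tree"
        )
    labels: list[str] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            where = nd.taxon.label if (nd.is_leaf() and nd.taxon) else "an internal node"
            raise ValueError(
                f"tree on line {lineno}: missing branch length above {where}"
            )
        if nd.is_leaf():
            if nd.taxon is None:
                raise ValueError(f"tree on line {lineno}: unlabeled tip")
            labels.append(nd.taxon.label)
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"tree on line {lineno}: duplicate tip labels {dupes}")


def read_newick(path: str | os.PathLike) -> list[dendropy.Tree]:
    """Read one rooted tree per line; a multi-line file is a tree sample.

    Branch lengths are required on all edges except the root edge (taken as 0
    when absent); trees whose root has more than two children are rejected.
    """
    trees: list[dendropy.Tree] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line, schema="newick", rooting="force-rooted",
                    taxon_namespace=dendropy.TaxonNamespace(),
                )
            except dendropy.utility.error.DataParseError as exc:
                if "Duplicate taxon labels" in str(exc):
                    raise ValueError(
                        f"tree on line {lineno}: duplicate tip labels ({exc})"
                    ) from exc
                raise ValueError(f"tree on line {lineno}: unparseable newick ({exc})") from exc
            _validate_tree(tree, lineno)
            if tree.seed_node.edge.length is None:
                tree.seed_node.edge.length = 0.0
            trees.append(tree)
    if not trees:
        raise ValueError(f"no trees in {path}")
    return trees


def write_newick(trees: Sequence[dendropy.Tree], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def read_traits(path: str | os.PathLike) -> dict[str, int]:
    """Read a tip trait table: CSV with columns ``tip_id, state`` (states 0/1)."""
    frame = pd.read_csv(path, dtype={"tip_id": str})
    missing = {"tip_id", "state"} - set(frame.columns)
    if missing:
        raise ValueError(f"trait table {path} missing columns: {sorted(missing)}")
    traits: dict[str, int] = {}
    for row in frame.itertuples(index=False):
        s = int(row.state)
        if s not in (0, 1):
            raise ValueError(f"trait state for {row.tip_id!r} must be 0/1, got {s}")
        if row.tip_id in traits:
            raise ValueError(f"duplicate tip id {row.tip_id!r} in {path}")
        traits[str(row.tip_id)] = s
    return traits


def write_traits(traits: dict[str, int], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"tip_id": list(traits.keys()), "state": list(traits.values())}
    ).to_csv(path, index=False)
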