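"""Readers and writers for the three on-disk formats the pipeline touches.

* FASTA protein sequences (:func:`read_fasta`, :func:`write_fasta`)
* 12-column tabular similarity hits, i.e. BLAST/DIAMOND ``-outfmt 6``
  (:func:`read_tabular_hits`, :func:`write_tabular_hits`)
* newick trees with branch lengths (:func:`parse_newick`)

Hit tables written here are interchangeable with DIAMOND output: the
downstream pipeline only depends on the 12-column schema.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, replace
from typing import Iterable

import dendropy

from .lg_data import AA_ORDER, AA_UNKNOWN

__all__ = [
    "Provenance",
    "ProteinRecord",
    "SimilarityHit",
    "PhyloTree",
    "FOUR_TAXON_TREE",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "parse_newick",
]

_CANONICAL = set(AA_ORDER)
# Non-canonical codes folded to X rather than rejected: real catalogues
# contain them and X is excluded from substitution scoring downstream.
_FOLD_TO_X = set("BZJUO*" + AA_UNKNOWN)

#: The fixed 4-taxon simulation tree (terminal branches 1, 3, 5 and 10,
#: negligible internal branches).
FOUR_TAXON_TREE = "(((Taxon1:1, Taxon2:3):0.1, Taxon3:5):0.1, Taxon4:10);"


class Provenance(str, enum.Enum):
    """Where a protein sequence came from."""

    ROOT = "root"
    SIMULATED = "simulated"
    REVERSED = "reversed"
    REAL = "real"


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with a provenance tag."""

    id: str
    sequence: str
    provenance: Provenance = Provenance.REAL
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        cleaned = []
        for ch in seq:
            if ch in _CANONICAL:
                cleaned.append(ch)
            elif ch in _FOLD_TO_X:
                cleaned.append(AA_UNKNOWN)
            else:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {ch!r}"
                )
        object.__setattr__(self, "sequence", "".join(cleaned))

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str, **changes) -> "ProteinRecord":
        return replace(self, sequence=sequence, **changes)


# outfmt 6 standard column order.
HIT_COLUMNS = (
    "query_id", "subject_id", "pident", "align_len", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class SimilarityHit:
    """One row of 12-column tabular similarity-search output."""

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if self.qstart < 1 or self.qstart > self.qend:
            raise ValueError("require 1 <= qstart <= qend")
        if self.sstart < 1 or self.sstart > self.send:
            raise ValueError("require 1 <= sstart <= send")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    def to_row(self) -> str:
        return "\t".join((
            self.query_id, self.subject_id,
            _num(self.pident), str(self.align_len), str(self.mismatches),
            str(self.gap_opens), str(self.qstart), str(self.qend),
            str(self.sstart), str(self.send),
            _num(self.evalue), _num(self.bitscore),
        ))


def _num(v: float) -> str:
    # repr() is the shortest decimal that round-trips for Python floats
    return repr(float(v))


class PhyloTree:
    """A rooted tree with per-edge branch lengths, thin wrapper over dendropy."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("terminal labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def terminal_branch_lengths(self) -> dict[str, float]:
        return {
            leaf.taxon.label: (leaf.edge.length or 0.0)
            for leaf in self._tree.leaf_node_iter()
        }

    def total_edge_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter()
        )

    def path_length(self, label: str) -> float:
        """Root-to-leaf path length for a terminal label."""
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                total, node = 0.0, leaf
                while node.parent_node is not None:
                    total += node.edge.length or 0.0
                    node = node.parent_node
                return total
        raise KeyError(label)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Terminal edges used by the simulator must carry branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise ValueError(
                f"terminal edge of {leaf.taxon.label!r} has no branch length"
            )
    return PhyloTree(tree)


def read_fasta(
    path: str | os.PathLike,
    provenance: Provenance = Provenance.REAL,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased and non-canonical residues folded to X.
    Duplicate ids and empty sequences are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise ValueError(f"{path}: empty header at line {header_line}")
        if rid in seen:
            raise ValueError(f"{path}: duplicate id {rid!r}")
        seq = "".join(chunks)
        if not seq:
            raise ValueError(
                f"{path}: record {rid!r} (line {header_line}) has no sequence"
            )
        seen.add(rid)
        records.append(ProteinRecord(rid, seq, provenance))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:]
                header_line = i
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: line {i}: sequence data before any '>' header"
                    )
                chunks.append(line)
        flush(-1)
    return records


def write_fasta(
    records: Iterable[ProteinRecord],
    path: str | os.PathLike,
    line_width: int = 60,
) -> None:
    """Write records as FASTA in input order at a fixed line width."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for start in range(0, len(seq), line_width):
                fh.write(seq[start:start + line_width] + "\n")


_INT_FIELDS = {"align_len", "mismatches", "gap_opens",
               "qstart", "qend", "sstart", "send"}


def read_tabular_hits(path: str | os.PathLike) -> list[SimilarityHit]:
    """Read 12-column tabular (outfmt 6) similarity hits, in file order."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: row {i}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            kwargs: dict = {}
            for name, value in zip(HIT_COLUMNS, parts):
                if name in ("query_id", "subject_id"):
                    kwargs[name] = value
                    continue
                try:
                    kwargs[name] = (
                        int(value) if name in _INT_FIELDS else float(value)
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {i}: non-numeric value {value!r} "
                        f"in column {name}"
                    ) from exc
            hits.append(SimilarityHit(**kwargs))
    return hits


def write_tabular_hits(
    hits: Iterable[SimilarityHit], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.to_row() + "\n")
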