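"""Readers and writers for the on-disk artifacts the pipeline touches.

All sequence I/O is plain text: FASTQ (Phred+33) for CCS reads, FASTA for
loci and consensus sequences, Newick for trees, and tab-separated tables for
reports.  Round-tripping is lossless: ``read_fastq(write_fastq(X)) == X``.

CCS pass counts travel in FASTQ headers as an ``np=<int>`` token (the
convention used by modern CCS FASTQ exports), defaulting to 1 when absent.
Sequences are uppercase-normalized on read; ``U`` becomes ``T`` and any
letter outside ``{A,C,G,T,N}`` becomes ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_NP_TOKEN = re.compile(r"\bnp=(\d+)\b")
_NOT_ACGTN = re.compile(r"[^ACGTN]")

DEFAULT_FASTA_WIDTH = 70


@dataclass(frozen=True)
class CCSRead:
    """One circular-consensus read with per-base qualities and a pass count."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    num_passes: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.num_passes < 1:
            raise ValueError(f"read {self.read_id!r}: num_passes < 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """An ordered list of equal-length gapped rows; gap character is '-'."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.sequence[j] for r in self.records)


def normalize_sequence(seq: str) -> str:
    """Uppercase; U->T; anything outside {A,C,G,T,N} -> N."""
    return _NOT_ACGTN.sub("N", seq.upper().replace("U", "T"))


def parse_pass_count(header: str) -> int:
    m = _NP_TOKEN.search(header)
    return int(m.group(1)) if m else 1


def read_fastq(path: str | Path) -> list[CCSRead]:
    """Parse a Phred+33 FASTQ into CCSReads, preserving input order.

    The pass count is taken from an ``np=<int>`` token anywhere in the
    header line, defaulting to 1.  A malformed 4-line block raises a
    ``ValueError`` naming the record index.
    """
    reads: list[CCSRead] = []
    with open(path) as handle:
        lines = handle.read().splitlines()
    # ignore trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ValueError(
            f"{path}: truncated FASTQ (record {len(lines) // 4} incomplete)"
        )
    for idx in range(0, len(lines), 4):
        rec_no = idx // 4
        head, seq, plus, qual = lines[idx : idx + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ block at record {rec_no}")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: record {rec_no}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        header = head[1:]
        read_id = header.split()[0] if header.split() else ""
        reads.append(
            CCSRead(
                read_id=read_id,
                sequence=normalize_sequence(seq),
                qualities=tuple(ord(c) - 33 for c in qual),
                num_passes=parse_pass_count(header),
            )
        )
    return reads


def write_fastq(reads: Iterable[CCSRead], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            out.write(f"@{r.read_id} np={r.num_passes}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path, *, normalize: bool = True) -> list[SequenceRecord]:
    """Parse FASTA into SequenceRecords.  Empty file -> empty list.

    Duplicate ids raise a ``ValueError`` listing them.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if normalize:
            seq = normalize_sequence(seq)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate record ids: {', '.join(dups)}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord | tuple[str, str]],
    path: str | Path,
    *,
    width: int = DEFAULT_FASTA_WIDTH,
) -> None:
    """Write FASTA wrapped at a fixed width (0 disables wrapping)."""
    with open(path, "w") as out:
        for rec in records:
            if isinstance(rec, tuple):
                rec = SequenceRecord(id=rec[0], sequence=rec[1])
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            out.write(head + "\n")
            seq = rec.sequence
            if width and width > 0:
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")
            else:
                out.write(seq + "\n")


def write_alignment_fasta(alignment: Alignment, path: str | Path) -> None:
    write_fasta(alignment.records, path)


# --- Newick ---------------------------------------------------------------


class TreeNode:
    """Minimal rooted tree node used to carry neighbor-joining output.

    Leaves have a ``name``; every node except the root has a ``branch_length``
    to its parent.
    """

    __slots__ = ("name", "branch_length", "children")

    def __init__(
        self,
        name: str | None = None,
        branch_length: float | None = None,
        children: Sequence["TreeNode"] | None = None,
    ) -> None:
        self.name = name
        self.branch_length = branch_length
        self.children: list[TreeNode] = list(children or [])

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name] if self.name else []
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


def _newick_label(node: TreeNode) -> str:
    if node.is_leaf():
        label = node.name or ""
    else:
        inner = ",".join(_newick_label(c) for c in node.children)
        label = f"({inner})"
    if node.branch_length is not None:
        label += f":{node.branch_length:g}"
    return label


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick; returns the string, optionally writing it."""
    text = _newick_label(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# --- TSV reports ----------------------------------------------------------


def write_tsv_report(
    rows: Iterable[Mapping[str, object] | Sequence[object]],
    path: str | Path,
    *,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a deterministic tab-separated table with a header line.

    ``rows`` may be mappings (columns inferred from the first row when not
    given) or pre-ordered sequences (``columns`` then required).
    """
    rows = list(rows)
    with open(path, "w") as out:
        if rows and isinstance(rows[0], Mapping):
            cols = list(columns) if columns else list(rows[0].keys())
            out.write("\t".join(cols) + "\n")
            for row in rows:
                out.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
        else:
            if columns is None:
                raise ValueError("columns required for sequence rows")
            out.write("\t".join(columns) + "\n")
            for row in rows:
                out.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        return []
    cols = lines[0].split("\t")
    return [dict(zip(cols, ln.split("\t"))) for ln in lines[1:]]
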