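"""File I/O: FASTA, Newick, TSV tables, and plain-text config files."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import GeneTree, TimeTree, Tree

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
]

_VALID_CHARS = frozenset("ACGTUNRYSWKMBDHVacgtunryswkmbdhv*-ACDEFGHIKLMNPQRSTVWYXacdefghiklmnpqrstvwyx")


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str
    description: str = ""


def read_fasta(path: Union[str, os.PathLike]) -> list[FastaRecord]:
    """Read a FASTA file into records; raises ValueError naming the bad line."""
    records = []
    with open(path) as handle:
        # Pre-scan for malformed content so errors carry a line number;
        # SeqIO is silently permissive about stray characters.
        handle.seek(0)
        seen_header = False
        for lineno, line in enumerate(handle, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
                if len(stripped) == 1:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
            else:
                if not seen_header:
                    raise ValueError(f"{path}: sequence before header at line {lineno}")
                bad = set(stripped) - _VALID_CHARS
                if bad:
                    raise ValueError(
                        f"{path}: invalid sequence characters {sorted(bad)} at line {lineno}"
                    )
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
            records.append(FastaRecord(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[FastaRecord], path: Union[str, os.PathLike], width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)
        for rec in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_newick(path: Union[str, os.PathLike], kind: str = "time") -> Tree:
    """Read one Newick tree from *path*.

    ``kind`` selects the returned type: "time" -> TimeTree, "gene" ->
    GeneTree, anything else -> plain Tree.
    """
    with open(path) as handle:
        text = handle.read().strip()
    if not text:
        raise ValueError(f"{path}: empty Newick file")
    cls = {"time": TimeTree, "gene": GeneTree}.get(kind, Tree)
    return cls.from_newick(text)


def write_newick(tree: Tree, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as handle:
        handle.write(tree.to_newick() + "\n")
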