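"""Sequence file I/O shared by every pipeline stage.

Thin wrappers around :mod:`Bio.SeqIO` that add transparent gzip handling,
uniform error messages with line numbers, and a plain ``(id, seq, qual)``
record tuple that the rest of the package uses instead of ``SeqRecord``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq


@dataclass(frozen=True)
class SeqEntry:
    """One sequence record: FASTA (qual is None) or FASTQ (phred scores)."""

    id: str
    seq: str
    qual: Optional[list[int]] = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


class SequenceParseError(ValueError):
    """Malformed FASTA/FASTQ input; message names the offending line."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: str | Path) -> str:
    """Return ``"fasta"`` or ``"fastq"`` from the first non-blank byte."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise SequenceParseError(
                    f"{path}: line 1: neither FASTA '>' nor FASTQ '@' header"
                )
    raise SequenceParseError(f"{path}: empty file")


def read_sequences(path: str | Path, fmt: Optional[str] = None) -> list[SeqEntry]:
    """Read FASTA/FASTQ (optionally gzipped) into a list of :class:`SeqEntry`.

    Raises :class:`SequenceParseError` naming the offending line on malformed
    or truncated records.
    """
    fmt = fmt or sniff_format(path)
    out: list[SeqEntry] = []
    with _open_text(path) as fh:
        if fmt == "fastq":
            _read_fastq(fh, path, out)
        else:
            for rec in SeqIO.parse(fh, "fasta"):
                out.append(SeqEntry(rec.id, str(rec.seq).upper()))
    return out


def _read_fastq(fh, path, out: list[SeqEntry]) -> None:
    # Manual 4-line parser so truncation errors can carry line numbers,
    # which Bio.SeqIO does not report.
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        if not header.strip():
            continue
        if not header.startswith("@"):
            raise SequenceParseError(f"{path}: line {lineno}: expected '@' header")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline().rstrip("\n")
        if not qual or not plus.startswith("+"):
            raise SequenceParseError(
                f"{path}: line {lineno}: truncated FASTQ record '{header.strip()}'"
            )
        lineno += 3
        if len(seq) != len(qual):
            raise SequenceParseError(
                f"{path}: line {lineno}: sequence/quality length mismatch"
            )
        out.append(
            SeqEntry(header[1:].split()[0], seq.upper(), [ord(c) - 33 for c in qual])
        )


def write_sequences(records: Iterable[SeqEntry], path: str | Path,
                    fmt: Optional[str] = None) -> None:
    """Write records as FASTA or FASTQ; gzip if the path ends in ``.gz``."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path, "wt") as fh:
        for r in records:
            if fmt == "fastq":
                qual = r.qual if r.qual is not None else [30] * len(r.seq)
                fh.write(f"@{r.id}\n{r.seq}\n+\n"
                         + "".join(chr(q + 33) for q in qual) + "\n")
            else:
                fh.write(f">{r.id}\n{r.seq}\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string in frame 0, trailing partial codon dropped."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())
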