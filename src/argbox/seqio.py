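"""Sequence and interval I/O, coordinate conventions, and strand utilities.

Conventions
-----------
* In memory, coordinates are 0-based half-open.  Everything that mirrors the
  printed operator table (and GFF3 output) is 1-based inclusive; BED output is
  0-based half-open.  The two conversions are ``start_bed = left - 1`` and
  ``end_bed = right``.
* Sequences are canonicalized to uppercase on input.  Non-ACGT symbols (N and
  other IUPAC ambiguity codes) are retained; downstream scoring skips any
  window that contains one.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "ALPHABET",
    "NucleotideSequence",
    "GenomicInterval",
    "AlphabetError",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "interval_length",
    "write_hits",
]

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains symbols outside {A, C, G, T}."""


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the canonical uppercase alphabet.

    ``residues`` may contain ambiguity symbols; :func:`is_canonical` tells
    whether the sequence is scorable at every position.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def is_canonical(self) -> bool:
        return all(c in ALPHABET for c in self.residues)

    def ambiguous_positions(self) -> list[int]:
        """0-based positions holding non-ACGT symbols."""
        return [i for i, c in enumerate(self.residues) if c not in ALPHABET]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic span, matching the printed coordinate style."""

    chrom: str
    left: int
    right: int
    strand: str = "."  # '+', '-' or '.' (unspecified)

    def __post_init__(self) -> None:
        if self.left < 1:
            raise ValueError(f"left coordinate must be >= 1, got {self.left}")
        if self.right < self.left:
            raise ValueError(
                f"invalid interval: right ({self.right}) < left ({self.left})"
            )
        if self.strand not in "+-.":
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.right - self.left + 1

    @property
    def bed_start(self) -> int:
        return self.left - 1

    @property
    def bed_end(self) -> int:
        return self.right

    @classmethod
    def from_bed(cls, chrom: str, start: int, end: int, strand: str = ".") -> "GenomicInterval":
        return cls(chrom, start + 1, end, strand)


def interval_length(iv: GenomicInterval) -> int:
    """Span length ``right - left + 1`` of a 1-based inclusive interval."""
    return len(iv)


def reverse_complement(s: NucleotideSequence | str) -> NucleotideSequence | str:
    """Watson-Crick reverse complement.

    Accepts and returns either a plain string or a :class:`NucleotideSequence`
    (the id is preserved).  Raises :class:`AlphabetError` on symbols outside
    A/C/G/T.
    """
    if isinstance(s, NucleotideSequence):
        return NucleotideSequence(s.id, str(_revcomp_str(s.residues)))
    return _revcomp_str(s)


def _revcomp_str(residues: str) -> str:
    bad = set(residues.upper()) - set(ALPHABET)
    if bad:
        raise AlphabetError(f"cannot reverse-complement symbols {sorted(bad)}")
    return str(Seq(residues.upper()).reverse_complement())


def read_fasta(path: str | os.PathLike) -> list[NucleotideSequence]:
    """Read a FASTA file into canonical uppercase records, order preserved.

    Raises :class:`FastaFormatError` for empty files or data appearing before
    the first header, naming the line number.
    """
    records: list[NucleotideSequence] = []
    name: str | None = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(NucleotideSequence(name, "".join(chunks)))
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before first '>' header at line {lineno}"
                    )
                chunks.append(line.strip())
    if name is not None:
        records.append(NucleotideSequence(name, "".join(chunks)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found (empty file?)")
    return records


def _open_text(path: str | os.PathLike, mode: str = "rt"):
    """Plain or gzip-compressed text, chosen by the .gz suffix."""
    if str(path).endswith(".gz"):
        import gzip

        return gzip.open(path, mode)
    return open(path, mode.rstrip("t"))


def write_fasta(records: list[NucleotideSequence], path: str | os.PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, max(len(rec.residues), 1), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_hits(hits, path: str | os.PathLike, format: str = "BED") -> None:
    """Write scan hits as BED6 or GFF3, deterministically sorted by (chrom, left).

    BED scores are ``round(Ri * 100)``; GFF3 carries ``Ri`` and ``pvalue``
    attributes.  ``hits`` are objects with ``interval``, ``strand``, ``ri``
    and ``p_value`` attributes (see :class:`argbox.scanner.ScanHit`).
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unknown hit format {format!r}; use 'BED' or 'GFF3'")
    ordered = sorted(hits, key=lambda h: (h.interval.chrom, h.interval.left, h.strand))
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
        else:
            fh.write('track name=argbox_hits description="ARG box scan hits"\n')
        for i, h in enumerate(ordered):
            iv = h.interval
            if fmt == "BED":
                score = int(round(h.ri * 100))
                fh.write(
                    f"{iv.chrom}\t{iv.bed_start}\t{iv.bed_end}\t"
                    f"hit{i + 1}\t{score}\t{h.strand}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\targbox\tbinding_site\t{iv.left}\t{iv.right}\t"
                    f"{h.ri:.3f}\t{h.strand}\t.\t"
                    f"ID=hit{i + 1};Ri={h.ri:.3f};pvalue={h.p_value:.3e}\n"
                )
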