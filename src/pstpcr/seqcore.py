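"""IUPAC-aware DNA sequence primitives and FASTA/TSV/BED input-output.

All coordinates are 0-based half-open (BED convention); human-readable
reports elsewhere in the package convert to 1-based inclusive. Case is
annotation only (lowercase marks the target-hybridizing part of a tailed
primer in the shipped tables); every comparison is case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = "ACGTRYSWKMBDHVN"

#: expansion of each IUPAC code into the plain bases it stands for
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

PRIMER_KINDS = ("PST", "SSP", "TAIL")


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class DegenerateSequenceError(ValueError):
    """A degenerate code appeared where a defined (ACGT) sequence is required."""


class ParseError(ValueError):
    """A record in an input file is malformed; the message names the line."""


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    """Check ``seq`` against the IUPAC DNA alphabet and return it unchanged.

    ``U`` is rejected rather than coerced to ``T``: this package is DNA-only.
    """
    if not isinstance(seq, str):
        raise AlphabetError(f"{name} must be a string, got {type(seq).__name__}")
    if len(seq) == 0:
        raise AlphabetError(f"{name} is empty")
    bad = set(seq.upper()) - set(IUPAC_DNA)
    if bad:
        raise AlphabetError(
            f"{name} contains non-IUPAC DNA character(s): {sorted(bad)!r}"
        )
    return seq


def validate_plain_dna(seq: str, *, name: str = "sequence") -> str:
    """Like :func:`validate_dna` but additionally rejects ambiguity codes."""
    validate_dna(seq, name=name)
    bad = set(seq.upper()) - set("ACGT")
    if bad:
        raise DegenerateSequenceError(
            f"{name} must be non-degenerate (ACGT only); found {sorted(bad)!r}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement with IUPAC codes mapped to their complements."""
    validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindrome(seq: str) -> bool:
    """True iff ``seq`` equals its own reverse complement.

    Palindromic here means self-reverse-complementary, as in a type II
    restriction recognition site; a true palindrome necessarily has even
    length. Defined sequences only: degenerate codes are rejected because
    primer target sites are fixed sequences.
    """
    validate_plain_dna(seq)
    if len(seq) % 2:
        return False
    return seq.upper() == reverse_complement(seq).upper()


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence (BED-compatible)."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file into ``[(id, sequence), ...]``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        try:
            validate_dna(seq, name=f"record {rec.id!r}")
        except AlphabetError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_primer_table(path: str | Path) -> pd.DataFrame:
    """Read a primer TSV with required columns id, sequence, kind, annotation.

    ``kind`` is one of PST | SSP | TAIL. Extra columns (e.g. published
    metrics) pass through untouched. Sequence case is preserved: lowercase
    marks the target-hybridizing region in SSP entries.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["id", "sequence", "kind", "annotation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for row_idx, row in df.iterrows():
        line_no = row_idx + 2  # header is line 1
        try:
            validate_dna(str(row["sequence"]), name="sequence")
        except AlphabetError as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
        if row["kind"] not in PRIMER_KINDS:
            raise ParseError(
                f"{path}, line {line_no}: kind must be one of {PRIMER_KINDS}, "
                f"got {row['kind']!r}"
            )
    return df


def write_primer_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[int] | None = None,
) -> None:
    """Write intervals as BED6 (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}, line {line_no}: fewer than 3 BED fields")
            try:
                strand = fields[5] if len(fields) >= 6 else "+"
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}, line {line_no}: {exc}") from exc
    return intervals
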