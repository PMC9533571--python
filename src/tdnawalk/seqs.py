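"""Small sequence and FASTA/FASTQ helpers shared by all modules."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= DNA_ALPHABET


def is_palindromic(motif: str) -> bool:
    """True if the motif equals its own reverse complement."""
    m = motif.upper()
    return m == revcomp(m)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly gzipped, wrapped or unwrapped) FASTA into a dict."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str] | Iterable[tuple[str, str]], width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with _open_text(path, "wt") as out:
        for name, seq in items:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) triples from a FASTQ file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with _open_text(path, "wt") as out:
        for name, seq, qual in reads:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")


def translate_to_codes(seq: str) -> "list[int]":
    """Map A/C/G/T to 0..3 (anything else to 4); used by the seed index."""
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    return [table.get(c, 4) for c in seq.upper()]


def as_seq(seq: str) -> Seq:
    return Seq(seq)
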