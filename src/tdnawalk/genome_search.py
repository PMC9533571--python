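"""Nucleotide search of genomic fragments against a reference genome.

A self-contained seed-and-extend search with extreme-value (Karlin-Altschul)
statistics, reproducing the high-identity query used for insertion-site
retrieval: exact-word seeding (default word size 11), gapped extension of the
seeded region with an explicit local aligner, and filtering at 95% identity
and an e-value ceiling of 1e-10. All passing placements of a fragment are
reported — in an allopolyploid, a single fragment legitimately matches its
locus on every homeologous subgenome, and those triplets are informative for
downstream homeolog resolution. A reader for the standard 12-column tabular
hit format lets an external search substitute for the internal one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tdnawalk.seqs import revcomp
from tdnawalk.vector_trim import (
    DEFAULT_SCORING,
    GenomicFragment,
    Scoring,
    _best_one_strand,
    _make_aligner,
    _summarise,
)

logger = logging.getLogger(__name__)

_BASE_CODES = np.full(256, 4, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _BASE_CODES[b] = i
for i, b in enumerate(b"acgt"):
    _BASE_CODES[b] = i


def _word_codes(seq: str, word_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every window of length word_size; windows containing
    a non-ACGT base are invalid."""
    codes = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - word_size + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    val = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for k in range(word_size):
        c = codes[k : k + n]
        val = val * 4 + np.where(c < 4, c, 0)
        valid &= c < 4
    return val, valid


class SeedIndex:
    """Exact-word lookup from any fixed-size word to all forward-strand genome
    positions, backed by a sorted word array (binary-search lookup)."""

    def __init__(self, genome: Mapping[str, str], word_size: int = 11):
        if word_size < 8:
            raise ValueError("word_size must be >= 8")
        self.word_size = word_size
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.chromosomes = list(self.genome)
        words_parts, chrom_parts, pos_parts = [], [], []
        for ci, name in enumerate(self.chromosomes):
            codes, valid = _word_codes(self.genome[name], word_size)
            idx = np.nonzero(valid)[0]
            words_parts.append(codes[idx])
            chrom_parts.append(np.full(len(idx), ci, dtype=np.int32))
            pos_parts.append(idx)
        words = np.concatenate(words_parts) if words_parts else np.empty(0, dtype=np.int64)
        if words.size == 0:
            raise ValueError("genome contains no indexable (non-N) words")
        self._chrom = np.concatenate(chrom_parts)
        self._pos = np.concatenate(pos_parts)
        order = np.argsort(words, kind="stable")
        self._sorted_words = words[order]
        self._order = order

    @property
    def n_words(self) -> int:
        return int(self._sorted_words.size)

    @property
    def db_length(self) -> int:
        return sum(len(s) for s in self.genome.values())

    def lookup(self, word: str) -> list[tuple[str, int]]:
        """All (chromosome, 0-based position) forward-strand occurrences."""
        if len(word) != self.word_size:
            raise ValueError(f"word must have length {self.word_size}")
        codes, valid = _word_codes(word, self.word_size)
        if not valid[0]:
            return []
        lo = np.searchsorted(self._sorted_words, codes[0], side="left")
        hi = np.searchsorted(self._sorted_words, codes[0], side="right")
        idx = self._order[lo:hi]
        hits = sorted((int(self._chrom[i]), int(self._pos[i])) for i in idx)
        return [(self.chromosomes[c], p) for c, p in hits]

    def _lookup_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised lookup: (query_offsets, chrom_indices, genome_positions)."""
        lo = np.searchsorted(self._sorted_words, codes, side="left")
        hi = np.searchsorted(self._sorted_words, codes, side="right")
        counts = hi - lo
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        qoff = np.repeat(nz, counts[nz])
        idx = np.concatenate([self._order[lo[i] : hi[i]] for i in nz])
        return qoff, self._chrom[idx], self._pos[idx]


def build_seed_index(genome: Mapping[str, str], word_size: int = 11) -> SeedIndex:
    return SeedIndex(genome, word_size)


@dataclass(frozen=True)
class KarlinParams:
    """Extreme-value parameters for ungapped nucleotide scoring (uniform base
    composition). lam and H are derived from the scoring scheme; K is the
    published constant for the default +2/-3 scheme and overridable."""

    lam: float
    K: float
    H: float


@lru_cache(maxsize=None)
def karlin_parameters(match: int = 2, mismatch: int = -3, K: float = 0.41) -> KarlinParams:
    """Solve sum_ij p_i p_j exp(lam * s_ij) = 1 for lam (uniform background)
    and derive the relative entropy H; K is taken as a constant."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lam = float(brentq(f, 1e-6, 10.0))
    q_match = 0.25 * math.exp(lam * match)
    q_mismatch = 0.75 * math.exp(lam * mismatch)
    H = lam * (q_match * match + q_mismatch * mismatch)
    return KarlinParams(lam=lam, K=K, H=H)


def bitscore(raw_score: float, params: KarlinParams) -> float:
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def evalue(
    score: float,
    query_len: int,
    db_len: int,
    params: KarlinParams,
    n_seqs: int = 1,
    length_correct: bool = True,
) -> float:
    """Expected number of chance alignments scoring >= score.

    E = K * m' * n' * exp(-lam * S), with the standard effective-length
    correction m' = m - l, n' = n - n_seqs * l, l = ln(K m n) / H (floored at
    1); disable with length_correct=False for the uncorrected linear form.
    """
    if not (math.isfinite(score) and query_len > 0 and db_len > 0):
        raise ValueError("score must be finite and lengths positive")
    m, n = float(query_len), float(db_len)
    if length_correct:
        ell = math.log(params.K * m * n) / params.H
        m = max(m - ell, 1.0)
        n = max(n - n_seqs * ell, 1.0)
    return params.K * m * n * math.exp(-params.lam * score)


@dataclass
class GenomeHit:
    """One match of a genomic fragment to the reference, in the 12-column
    tabular convention: 1-based inclusive coordinates, qstart < qend always,
    sstart > send on the minus strand."""

    fragment_id: str
    chromosome: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str
    qlen: int
    raw_score: int = 0
    read_id: str = ""
    which_read: int = 0
    border: str = ""
    walking_primer_id: str = ""
    line_id: str = ""
    clip_side: str = ""
    vector_id: str = ""

    @property
    def s_lo(self) -> int:
        return min(self.sstart, self.send)

    @property
    def s_hi(self) -> int:
        return max(self.sstart, self.send)


@dataclass(frozen=True)
class SearchParams:
    min_identity: float = 95.0
    max_evalue: float = 1e-10
    word_size: int = 11
    scoring: Scoring = DEFAULT_SCORING
    seed_pad: int = 20
    karlin_K: float = 0.41


def _merge_regions(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int, int]]:
    """Merge overlapping candidate regions; returns (start, end, n_seeds)."""
    order = np.argsort(starts)
    merged: list[list[int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
            merged[-1][2] += 1
        else:
            merged.append([int(s), int(e), 1])
    return [(s, e, c) for s, e, c in merged]


def _search_one_orientation(
    oriented: str,
    strand: str,
    frag: GenomicFragment,
    index: SeedIndex,
    params: SearchParams,
    kp: KarlinParams,
    aligner,
) -> list[GenomeHit]:
    codes, valid = _word_codes(oriented, params.word_size)
    if codes.size == 0:
        return []
    codes = codes[valid]
    qpos_all = np.nonzero(valid)[0]
    qoff, chrom_idx, gpos = index._lookup_codes(codes)
    if qoff.size == 0:
        return []
    qpos = qpos_all[qoff]
    implied_start = gpos - qpos
    qlen = len(oriented)
    # two-hit seeding: a region needs two word matches before extension,
    # unless the fragment is so short it offers few words at all
    min_seeds = 2 if codes.size >= 4 else 1
    hits: list[GenomeHit] = []
    for ci in np.unique(chrom_idx):
        chrom = index.chromosomes[ci]
        sel = chrom_idx == ci
        starts = implied_start[sel] - params.seed_pad
        ends = implied_start[sel] + qlen + params.seed_pad
        for lo, hi, n_seeds in _merge_regions(starts, ends):
            if n_seeds < min_seeds:
                continue
            lo = max(lo, 0)
            hi = min(hi, len(index.genome[chrom]))
            window = index.genome[chrom][lo:hi]
            res = _best_one_strand(aligner, window, oriented)
            if res is None:
                continue
            _, aln = res
            matches, mismatches, gap_opens, gaps, ref_iv, q_iv = _summarise(aln, window, oriented)
            align_len = matches + mismatches + gaps
            if align_len == 0:
                continue
            pident = 100.0 * matches / align_len
            e = evalue(aln.score, qlen, index.db_length, kp, n_seqs=len(index.chromosomes))
            if pident < params.min_identity or e > params.max_evalue:
                continue
            s0, s1 = lo + ref_iv[0], lo + ref_iv[1]  # 0-based half-open on genome
            if strand == "+":
                sstart, send = s0 + 1, s1
                qstart, qend = q_iv[0] + 1, q_iv[1]
            else:
                sstart, send = s1, s0 + 1
                qstart, qend = qlen - q_iv[1] + 1, qlen - q_iv[0]
            hits.append(
                GenomeHit(
                    fragment_id=frag.fragment_id,
                    chromosome=chrom,
                    pident=pident,
                    length=align_len,
                    mismatch=mismatches,
                    gapopen=gap_opens,
                    qstart=qstart,
                    qend=qend,
                    sstart=sstart,
                    send=send,
                    evalue=e,
                    bitscore=bitscore(aln.score, kp),
                    strand=strand,
                    qlen=qlen,
                    raw_score=int(aln.score),
                    read_id=frag.read_id,
                    which_read=frag.which_read,
                    border=frag.library.border,
                    walking_primer_id=frag.library.walking_primer_id,
                    line_id=frag.library.line_id,
                    clip_side=frag.clip_side,
                    vector_id=frag.vector_id or "",
                )
            )
    return hits


def _drop_redundant(hits: list[GenomeHit]) -> list[GenomeHit]:
    """Keep locally maximal non-overlapping placements per fragment."""
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.chromosome, h.s_lo))
    kept: list[GenomeHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if k.chromosome != h.chromosome:
                continue
            ov = min(k.s_hi, h.s_hi) - max(k.s_lo, h.s_lo) + 1
            if ov > 0.5 * min(k.s_hi - k.s_lo + 1, h.s_hi - h.s_lo + 1):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def search_genome(
    fragments: Sequence[GenomicFragment],
    index: SeedIndex,
    params: SearchParams = SearchParams(),
) -> list[GenomeHit]:
    """Search every fragment against the indexed genome.

    Fragments shorter than the word size are skipped (with a logged count).
    Results are sorted by (fragment input order, e-value ascending).
    """
    kp = karlin_parameters(params.scoring.match, params.scoring.mismatch, params.karlin_K)
    aligner = _make_aligner(params.scoring)
    results: list[GenomeHit] = []
    n_skipped = 0
    for fi, frag in enumerate(fragments):
        seq = frag.sequence.upper()
        if len(seq) < params.word_size:
            n_skipped += 1
            continue
        frag_hits: list[GenomeHit] = []
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            frag_hits.extend(
                _search_one_orientation(oriented, strand, frag, index, params, kp, aligner)
            )
        frag_hits = _drop_redundant(frag_hits)
        frag_hits.sort(key=lambda h: (h.evalue, h.chromosome, h.s_lo))
        results.extend(frag_hits)
    if n_skipped:
        logger.info("search_genome: skipped %d fragments shorter than word size", n_skipped)
    return results


_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_PROV_COLUMNS = [
    "strand", "qlen", "read_id", "which_read", "border",
    "walking_primer_id", "line_id", "clip_side", "vector_id",
]


def hits_to_frame(hits: Sequence[GenomeHit]) -> pd.DataFrame:
    rows = [
        {
            "qseqid": h.fragment_id, "sseqid": h.chromosome, "pident": round(h.pident, 3),
            "length": h.length, "mismatch": h.mismatch, "gapopen": h.gapopen,
            "qstart": h.qstart, "qend": h.qend, "sstart": h.sstart, "send": h.send,
            "evalue": h.evalue, "bitscore": round(h.bitscore, 1),
            "strand": h.strand, "qlen": h.qlen, "read_id": h.read_id,
            "which_read": h.which_read, "border": h.border,
            "walking_primer_id": h.walking_primer_id, "line_id": h.line_id,
            "clip_side": h.clip_side, "vector_id": h.vector_id,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=_HIT_COLUMNS + _PROV_COLUMNS)


def write_hits_tsv(path: str | Path, hits: Sequence[GenomeHit]) -> None:
    """12-column tabular hits (1-based inclusive subject coordinates) plus
    provenance columns."""
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[GenomeHit]:
    """Import hits from the 12-column tabular dialect (header optional;
    provenance columns used when present). Allows substituting an external
    nucleotide search for the internal one."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]) == "qseqid"
    df = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=None if has_header else _HIT_COLUMNS,
    )
    hits = []
    for _, r in df.iterrows():
        sstart, send = int(r["sstart"]), int(r["send"])
        hits.append(
            GenomeHit(
                fragment_id=str(r["qseqid"]),
                chromosome=str(r["sseqid"]),
                pident=float(r["pident"]),
                length=int(r["length"]),
                mismatch=int(r["mismatch"]),
                gapopen=int(r["gapopen"]),
                qstart=int(r["qstart"]),
                qend=int(r["qend"]),
                sstart=sstart,
                send=send,
                evalue=float(r["evalue"]),
                bitscore=float(r["bitscore"]),
                strand=str(r.get("strand", "+" if send >= sstart else "-")),
                qlen=int(r.get("qlen", max(int(r["qstart"]), int(r["qend"])))),
                read_id=str(r.get("read_id", "")),
                which_read=int(r.get("which_read", 0) or 0),
                border=str(r.get("border", "")),
                walking_primer_id=str(r.get("walking_primer_id", "")),
                line_id=str(r.get("line_id", "")),
                clip_side=str(r.get("clip_side", "")),
                vector_id=str(r.get("vector_id", "")),
            )
        )
    return hits
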