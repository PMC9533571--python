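"""Recover plant-genomic fragments from T-DNA junction amplicon reads.

In the walking-PCR library, read 2 of every informative pair begins inside
the transgene near the left or right border and runs across the junction into
the plant genome; read 1 begins at the walking primer and may or may not
reach the T-DNA. This module aligns reads locally to the T-DNA vector,
applies a score-and-margin confidence filter (the mapping-quality analog for
an explicit local aligner), and emits the unaligned border-distal read
terminus — the plant-genomic arm — as a fragment for genome searching. A
read 1 with no credible vector alignment is emitted whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import edlib
from Bio import Align

from tdnawalk.seqs import revcomp


@dataclass(frozen=True)
class Scoring:
    """Local alignment scoring. A gap of length k scores gap_open + k * gap_extend
    (penalties are negative), matching the usual nucleotide-search convention."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class LibraryMeta:
    """Provenance of one PCR library: transgenic line, targeted border, and
    walking primer (PST1..PST4 or the pooled reaction)."""

    line_id: str
    border: str  # "LB" or "RB"
    walking_primer_id: str

    def __post_init__(self):
        if self.border not in ("LB", "RB"):
            raise ValueError(f"border must be LB or RB, got {self.border!r}")


@dataclass
class ReadPair:
    id: str
    read1_seq: str
    read2_seq: str
    library: LibraryMeta
    read1_qual: Optional[str] = None
    read2_qual: Optional[str] = None


@dataclass
class LocalAlignment:
    """Best local alignment of a query against a reference, considering both
    query orientations. Intervals are 0-based half-open; the query interval is
    given in original (input) query coordinates even for minus-strand hits."""

    score: int
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    strand: str  # "+" or "-" (query orientation relative to reference)
    identity: float  # percent of alignment columns that match
    matches: int
    mismatches: int
    gap_opens: int
    gaps: int
    align_length: int


@dataclass
class VectorAlignmentRecord:
    read_id: str
    which_read: int
    vector_id: str
    alignment: LocalAlignment
    accepted: bool
    margin: float = 0.0


@dataclass
class GenomicFragment:
    """Candidate plant-genomic sequence recovered from a read, with provenance."""

    sequence: str
    read_id: str
    which_read: int
    clip_side: str  # border_distal_5prime | border_distal_3prime | whole_unmapped_mate
    library: LibraryMeta
    vector_id: Optional[str] = None

    @property
    def fragment_id(self) -> str:
        return (
            f"{self.read_id}|r{self.which_read}|{self.library.border}|"
            f"{self.library.walking_primer_id}|{self.clip_side}"
        )


@dataclass
class ClassifiedPair:
    pair: ReadPair
    read2_record: VectorAlignmentRecord
    read1_record: Optional[VectorAlignmentRecord]

    @property
    def vector_id(self) -> str:
        return self.read2_record.vector_id


@dataclass
class Rejection:
    read_id: str
    reason: str


def trim_adapter(read: str, adapter: str, min_overlap: int = 8, max_mismatch_frac: float = 0.10) -> str:
    """Remove 3' adapter read-through.

    The longest 3'-terminal suffix that begins with the adapter — an overlap
    of at least ``min_overlap`` bases against the adapter prefix with at most
    ``max_mismatch_frac`` mismatches — is removed in full (anything beyond
    the matched adapter is read-through noise, not insert). Reads with no
    such suffix are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read_u, adapter_u = read.upper(), adapter.upper()
    for i in range(len(read_u) - min_overlap + 1):
        overlap = min(len(read_u) - i, len(adapter_u))
        allowed = int(max_mismatch_frac * overlap)
        mism = 0
        for a, b in zip(read_u[i : i + overlap], adapter_u):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return read[:i]
    return read


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gap base; fold one
    # extension in so a length-k gap scores gap_open + k * gap_extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _summarise(alignment, reference: str, oriented_query: str) -> tuple[int, int, int, int, tuple[int, int], tuple[int, int]]:
    """(matches, mismatches, gap_opens, gaps, ref_interval, query_interval)."""
    ref_blocks, q_blocks = alignment.aligned
    matches = mismatches = gap_opens = gaps = 0
    prev_r_end = prev_q_end = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        if prev_r_end is not None:
            dr, dq = rs - prev_r_end, qs - prev_q_end
            if dr > 0:
                gap_opens += 1
                gaps += dr
            if dq > 0:
                gap_opens += 1
                gaps += dq
        for a, b in zip(reference[rs:re_], oriented_query[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_r_end, prev_q_end = re_, qe
    ref_iv = (int(ref_blocks[0][0]), int(ref_blocks[-1][1]))
    q_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return matches, mismatches, gap_opens, gaps, ref_iv, q_iv


def _best_one_strand(aligner, reference: str, query: str) -> Optional[tuple[float, object]]:
    if not reference or not query:
        return None
    alignments = aligner.align(reference, query)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    return best.score, best


def local_align(
    query: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> Optional[LocalAlignment]:
    """Maximal-scoring local alignment of ``query`` against ``reference``.

    Both query orientations are considered; ties break toward the lower
    reference start and then the forward strand. Returns None when no
    positive-scoring alignment exists.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    query_u, reference_u = query.upper(), reference.upper()
    aligner = _make_aligner(scoring)
    candidates = []
    for strand, oriented in (("+", query_u), ("-", revcomp(query_u))):
        res = _best_one_strand(aligner, reference_u, oriented)
        if res is not None:
            score, aln = res
            ref_start = int(aln.aligned[0][0][0])
            candidates.append((-score, ref_start, 0 if strand == "+" else 1, strand, oriented, aln))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])
    _, _, _, strand, oriented, aln = candidates[0]
    matches, mismatches, gap_opens, gaps, ref_iv, q_iv = _summarise(aln, reference_u, oriented)
    if strand == "-":
        n = len(query_u)
        q_iv = (n - q_iv[1], n - q_iv[0])
    align_length = matches + mismatches + gaps
    return LocalAlignment(
        score=int(aln.score),
        ref_interval=ref_iv,
        query_interval=q_iv,
        strand=strand,
        identity=100.0 * matches / align_length if align_length else 0.0,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gaps=gaps,
        align_length=align_length,
    )


def _align_in_window(
    aligner, query_oriented: str, reference: str, window: tuple[int, int]
) -> Optional[tuple[float, object, int]]:
    """Exact local alignment of an oriented query inside a reference window;
    returns (score, alignment, window offset)."""
    lo, hi = max(0, window[0]), min(len(reference), window[1])
    if hi - lo < 8:
        return None
    res = _best_one_strand(aligner, reference[lo:hi], query_oriented)
    if res is None:
        return None
    return res[0], res[1], lo


def fast_local_align(
    query: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    pad: int = 40,
) -> Optional[LocalAlignment]:
    """Windowed local alignment for long references.

    A bit-parallel edit-distance scan (infix mode) locates the best-matching
    reference region for each query orientation; the region, padded by
    ``pad`` bp, is then scored exactly with the same local aligner as
    :func:`local_align`. Equivalent to the exact search whenever the
    edit-distance optimum and the score optimum coincide, which holds for
    reads with one credible vector placement; ambiguous placements are
    handled by the caller's margin logic.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    query_u, reference_u = query.upper(), reference.upper()
    aligner = _make_aligner(scoring)
    candidates = []
    for strand, oriented in (("+", query_u), ("-", revcomp(query_u))):
        loc = edlib.align(oriented, reference_u, mode="HW", task="locations")
        locations = loc.get("locations") or []
        if not locations:
            continue
        start, end = locations[0]
        res = _align_in_window(aligner, oriented, reference_u, (int(start) - pad, int(end) + 1 + pad))
        if res is None:
            continue
        score, aln, offset = res
        ref_start = offset + int(aln.aligned[0][0][0])
        candidates.append((-score, ref_start, 0 if strand == "+" else 1, strand, oriented, aln, offset))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])
    _, _, _, strand, oriented, aln, offset = candidates[0]
    matches, mismatches, gap_opens, gaps, ref_iv, q_iv = _summarise(
        aln, reference_u[offset:], oriented
    )
    ref_iv = (ref_iv[0] + offset, ref_iv[1] + offset)
    if strand == "-":
        n = len(query_u)
        q_iv = (n - q_iv[1], n - q_iv[0])
    align_length = matches + mismatches + gaps
    return LocalAlignment(
        score=int(aln.score),
        ref_interval=ref_iv,
        query_interval=q_iv,
        strand=strand,
        identity=100.0 * matches / align_length if align_length else 0.0,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gaps=gaps,
        align_length=align_length,
    )


def _second_best_score(
    read: str,
    vectors: Mapping[str, str],
    best_vector: str,
    best_iv: tuple[int, int],
    per_vector_best: Mapping[str, Optional[LocalAlignment]],
    scoring: Scoring,
) -> float:
    """Best competing placement: any other vector, or the best vector with the
    winning interval excised (catches repeats present twice in one vector)."""
    competitors = [
        aln.score for vid, aln in per_vector_best.items() if vid != best_vector and aln is not None
    ]
    vseq = vectors[best_vector]
    for piece in (vseq[: best_iv[0]], vseq[best_iv[1] :]):
        if len(piece) >= 10:
            aln = fast_local_align(read, piece, scoring)
            if aln is not None:
                competitors.append(aln.score)
    return max(competitors, default=0.0)


def classify_read_pair(
    pair: ReadPair,
    vectors: Mapping[str, str] | str,
    min_score: float = 40.0,
    min_margin: float = 10.0,
    min_read_len: int = 20,
    scoring: Scoring = DEFAULT_SCORING,
) -> ClassifiedPair | Rejection:
    """Retain a pair only if read 2 aligns confidently to a T-DNA vector.

    Confidence requires score >= min_score and a best-minus-second-best score
    margin >= min_margin (the MAPQ>10 analog: an ambiguous placement, e.g. a
    repeat present twice in the vector, yields margin 0 and is rejected).
    Read 1 of an accepted pair is then aligned and recorded whether or not it
    maps.
    """
    if isinstance(vectors, str):
        vectors = {"vector": vectors}
    if len(pair.read2_seq) < min_read_len or len(pair.read1_seq) < min_read_len:
        return Rejection(pair.id, "too_short")
    per_vector: dict[str, Optional[LocalAlignment]] = {
        vid: fast_local_align(pair.read2_seq, vseq, scoring) for vid, vseq in vectors.items()
    }
    scored = [(aln.score, vid) for vid, aln in per_vector.items() if aln is not None]
    if not scored:
        return Rejection(pair.id, "no_vector_alignment")
    best_score, best_vid = max(scored)
    best_aln = per_vector[best_vid]
    if best_score < min_score:
        return Rejection(pair.id, "no_vector_alignment")
    second = _second_best_score(
        pair.read2_seq, vectors, best_vid, best_aln.ref_interval, per_vector, scoring
    )
    margin = best_score - second
    if margin < min_margin:
        return Rejection(pair.id, "ambiguous_vector_alignment")
    rec2 = VectorAlignmentRecord(
        read_id=pair.id, which_read=2, vector_id=best_vid,
        alignment=best_aln, accepted=True, margin=margin,
    )
    aln1 = fast_local_align(pair.read1_seq, vectors[best_vid], scoring)
    rec1 = None
    if aln1 is not None:
        rec1 = VectorAlignmentRecord(
            read_id=pair.id, which_read=1, vector_id=best_vid,
            alignment=aln1, accepted=aln1.score >= min_score,
        )
    return ClassifiedPair(pair=pair, read2_record=rec2, read1_record=rec1)


DEFAULT_BORDER_LOCATION = {"LB": "start", "RB": "end"}


def _border_distal_side(border_location: str, strand: str) -> str:
    """Which read terminus points away from the border into the plant genome.

    The genomic arm continues past the border end of the vector: for a border
    at the vector start, a forward-aligned read reaches the genome through its
    5' terminus (the classic 5'-clip-for-LB rule); a reverse-aligned read
    through its 3' terminus, and mirrored for a border at the vector end.
    """
    if border_location == "start":
        return "border_distal_5prime" if strand == "+" else "border_distal_3prime"
    return "border_distal_3prime" if strand == "+" else "border_distal_5prime"


def extract_genomic_fragments(
    classified: ClassifiedPair,
    min_len: int = 20,
    border_location: Mapping[str, str] = DEFAULT_BORDER_LOCATION,
) -> list[GenomicFragment]:
    """Emit the border-distal unaligned terminus of each vector-aligned read,
    and the whole read 1 when it has no acceptable vector alignment.

    Segments shorter than ``min_len`` (default 20 bp) are discarded.
    """
    border = classified.pair.library.border
    loc = border_location[border]
    out: list[GenomicFragment] = []

    def clip_from(record: VectorAlignmentRecord, seq: str) -> None:
        side = _border_distal_side(loc, record.alignment.strand)
        qs, qe = record.alignment.query_interval
        fragment = seq[:qs] if side == "border_distal_5prime" else seq[qe:]
        if len(fragment) >= min_len:
            out.append(
                GenomicFragment(
                    sequence=fragment,
                    read_id=classified.pair.id,
                    which_read=record.which_read,
                    clip_side=side,
                    library=classified.pair.library,
                    vector_id=classified.vector_id,
                )
            )

    clip_from(classified.read2_record, classified.pair.read2_seq)
    rec1 = classified.read1_record
    if rec1 is not None and rec1.accepted:
        clip_from(rec1, classified.pair.read1_seq)
    elif len(classified.pair.read1_seq) >= min_len:
        out.append(
            GenomicFragment(
                sequence=classified.pair.read1_seq,
                read_id=classified.pair.id,
                which_read=1,
                clip_side="whole_unmapped_mate",
                library=classified.pair.library,
                vector_id=classified.vector_id,
            )
        )
    return out


def dedupe_fragments(fragments: Sequence[GenomicFragment]) -> list[GenomicFragment]:
    """Keep one representative (the first occurrence) per distinct sequence."""
    seen: set[str] = set()
    out: list[GenomicFragment] = []
    for frag in fragments:
        if frag.sequence not in seen:
            seen.add(frag.sequence)
            out.append(frag)
    return out
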