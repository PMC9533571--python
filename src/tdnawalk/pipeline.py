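"""End-to-end orchestration: trim -> search -> call-sites -> report.

The library entry point is :func:`detect_insertions`, which takes in-memory
read pairs and sequences; :func:`run_detect` is the file-based equivalent
used by the command line, reading paired FASTQ + vector/genome FASTA + a
library sheet and writing the candidate-site report, fragments FASTA, hits
TSV, BED, primer windows and a JSON metrics file. Identical inputs produce
byte-identical outputs.

Coordinate conventions: TSV reports are 1-based inclusive, BED is 0-based
half-open; every output table states its convention in a header line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from tdnawalk.genome_search import (
    GenomeHit,
    SearchParams,
    build_seed_index,
    search_genome,
    write_hits_tsv,
)
from tdnawalk.seqs import read_fasta, read_fastq, write_fasta
from tdnawalk.simulator import ADAPTER_R1, ADAPTER_R2
from tdnawalk.site_caller import (
    CandidateSite,
    Hotspot,
    cluster_hits,
    flag_and_rank,
    primer_windows,
    write_sites_bed,
    write_sites_tsv,
)
from tdnawalk.vector_trim import (
    ClassifiedPair,
    GenomicFragment,
    LibraryMeta,
    ReadPair,
    Rejection,
    classify_read_pair,
    dedupe_fragments,
    extract_genomic_fragments,
    trim_adapter,
)
from tdnawalk.zygosity import (
    calls_frame,
    read_genotype_sheet,
    summarize_segregation,
    summary_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class DetectParams:
    """Pipeline thresholds. Values with an established provenance: 20 bp
    minimum clip, 95% identity and 1e-10 e-value search filters, 1 kb
    clustering/pairing gap, 1e-30 / 99% / 60 bp ranking criteria. The rest
    are this package's documented defaults."""

    min_clip: int = 20
    min_score: float = 40.0
    min_margin: float = 10.0
    min_identity: float = 95.0
    max_evalue: float = 1e-10
    word_size: int = 11
    cluster_gap: int = 1000
    strong_evalue: float = 1e-30
    strong_identity: float = 99.0
    long_read_len: int = 60
    pooled_counts_as_library: bool = True
    adapters: tuple[str, str] = (ADAPTER_R1, ADAPTER_R2)


@dataclass
class DetectionResult:
    sites_by_line: dict[str, list[CandidateSite]]
    hotspots_by_line: dict[str, list[Hotspot]]
    hits: list[GenomeHit]
    fragments: list[GenomicFragment]
    metrics: dict

    @property
    def sites(self) -> list[CandidateSite]:
        return [s for sites in self.sites_by_line.values() for s in sites]


def detect_insertions(
    read_pairs: Sequence[ReadPair],
    vectors: Mapping[str, str] | str,
    genome: Mapping[str, str],
    params: DetectParams = DetectParams(),
) -> DetectionResult:
    """Run the full detection pipeline on in-memory reads.

    Lines present in the read metadata are processed independently and then
    compared against one another for the cross-line uniqueness flag.
    """
    if isinstance(vectors, str):
        vectors = {"vector": vectors}
    metrics: dict = {"pairs_in": len(read_pairs), "rejections": {}}
    fragments: list[GenomicFragment] = []
    n_accepted = 0
    # classification depends only on the read sequences, so PCR duplicates
    # and error-free copies of the same amplicon are classified once
    cache: dict[tuple[str, str], ClassifiedPair | Rejection] = {}
    for pair in read_pairs:
        r1 = pair.read1_seq
        r2 = pair.read2_seq
        for adapter in params.adapters:
            r1 = trim_adapter(r1, adapter)
            r2 = trim_adapter(r2, adapter)
        trimmed = ReadPair(pair.id, r1, r2, pair.library, pair.read1_qual, pair.read2_qual)
        key = (r1, r2)
        cached = cache.get(key)
        if cached is None:
            cached = classify_read_pair(
                trimmed, vectors, min_score=params.min_score, min_margin=params.min_margin
            )
            cache[key] = cached
        outcome = cached
        if not isinstance(outcome, Rejection):
            outcome = ClassifiedPair(
                pair=trimmed,
                read2_record=outcome.read2_record,
                read1_record=outcome.read1_record,
            )
        if isinstance(outcome, Rejection):
            metrics["rejections"][outcome.reason] = metrics["rejections"].get(outcome.reason, 0) + 1
            continue
        n_accepted += 1
        fragments.extend(extract_genomic_fragments(outcome, min_len=params.min_clip))
    metrics["pairs_accepted"] = n_accepted
    metrics["fragments_emitted"] = len(fragments)
    fragments = dedupe_fragments(fragments)
    metrics["fragments_unique"] = len(fragments)

    hits: list[GenomeHit] = []
    if fragments:
        index = build_seed_index(genome, params.word_size)
        hits = search_genome(
            fragments,
            index,
            SearchParams(
                min_identity=params.min_identity,
                max_evalue=params.max_evalue,
                word_size=params.word_size,
            ),
        )
    metrics["hits"] = len(hits)

    hits_by_line: dict[str, list[GenomeHit]] = {}
    for h in hits:
        hits_by_line.setdefault(h.line_id, []).append(h)
    hotspots_by_line = {
        line: cluster_hits(line_hits, gap=params.cluster_gap)
        for line, line_hits in sorted(hits_by_line.items())
    }
    metrics["hotspots"] = {line: len(hs) for line, hs in hotspots_by_line.items()}
    sites_by_line: dict[str, list[CandidateSite]] = {}
    for line, hotspots in hotspots_by_line.items():
        others = [hs for other, hs in hotspots_by_line.items() if other != line]
        sites_by_line[line] = flag_and_rank(
            hotspots,
            other_lines=others,
            gap=params.cluster_gap,
            strong_evalue=params.strong_evalue,
            strong_identity=params.strong_identity,
            long_read_len=params.long_read_len,
            pooled_counts_as_library=params.pooled_counts_as_library,
        )
    metrics["candidates"] = {line: len(s) for line, s in sites_by_line.items()}
    return DetectionResult(
        sites_by_line=sites_by_line,
        hotspots_by_line=hotspots_by_line,
        hits=hits,
        fragments=fragments,
        metrics=metrics,
    )


@dataclass
class RunConfig:
    """File-based run configuration (CLI flags override config-file values)."""

    reads_r1: Path
    reads_r2: Path
    vector_fasta: Path
    genome_fasta: Path
    library_sheet: Path
    outdir: Path
    params: DetectParams = field(default_factory=DetectParams)


def load_read_pairs(
    reads_r1: str | Path,
    reads_r2: str | Path,
    library_sheet: str | Path,
) -> list[ReadPair]:
    """Pair up two FASTQ files using the library sheet.

    A sheet with a ``read_id`` column assigns metadata per read; otherwise a
    single row (line_id, border, walking_primer_id) applies to both files.
    """
    sheet = pd.read_csv(library_sheet, sep="\t", dtype=str)
    per_read: Optional[dict[str, LibraryMeta]] = None
    default_meta: Optional[LibraryMeta] = None
    if "read_id" in sheet.columns:
        per_read = {
            str(r["read_id"]): LibraryMeta(str(r["line_id"]), str(r["border"]), str(r["walking_primer_id"]))
            for _, r in sheet.iterrows()
        }
    else:
        if len(sheet) != 1:
            raise ValueError("library sheet without read_id column must have exactly one row")
        r = sheet.iloc[0]
        default_meta = LibraryMeta(str(r["line_id"]), str(r["border"]), str(r["walking_primer_id"]))
    pairs = []
    r2_reads = {rid: (seq, qual) for rid, seq, qual in read_fastq(reads_r2)}
    for rid, seq1, qual1 in read_fastq(reads_r1):
        if rid not in r2_reads:
            raise ValueError(f"read {rid} present in R1 but not R2")
        seq2, qual2 = r2_reads[rid]
        meta = per_read.get(rid) if per_read else default_meta
        if meta is None:
            raise ValueError(f"no library metadata for read {rid}")
        pairs.append(ReadPair(rid, seq1, seq2, meta, qual1, qual2))
    return pairs


def write_fragments_fasta(path: str | Path, fragments: Sequence[GenomicFragment]) -> None:
    """Headers encode provenance: readid|r1/r2|line|border|primer|clipside."""
    records = [
        (
            f"{f.read_id}|r{f.which_read}|{f.library.line_id}|{f.library.border}|"
            f"{f.library.walking_primer_id}|{f.clip_side}",
            f.sequence,
        )
        for f in fragments
    ]
    write_fasta(path, records)


def read_fragments_fasta(path: str | Path) -> list[GenomicFragment]:
    fragments = []
    for header, seq in read_fasta(path).items():
        fields = header.split("|")
        if len(fields) != 6:
            raise ValueError(f"fragment header {header!r} does not encode provenance")
        read_id, which, line, border, primer, clip = fields
        fragments.append(
            GenomicFragment(
                sequence=seq,
                read_id=read_id,
                which_read=int(which.lstrip("r")),
                clip_side=clip,
                library=LibraryMeta(line, border, primer),
            )
        )
    return fragments


def run_detect(config: RunConfig) -> DetectionResult:
    """Execute the pipeline from files and write all outputs.

    Writes: fragments.fa, hits.tsv, sites.tsv, sites.bed, primer_windows.fa
    and metrics.json under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        pairs = load_read_pairs(config.reads_r1, config.reads_r2, config.library_sheet)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    vectors = read_fasta(config.vector_fasta)
    genome = read_fasta(config.genome_fasta)
    if not pairs:
        logger.warning("no read pairs in input; writing empty report")
    try:
        result = detect_insertions(pairs, vectors, genome, config.params)
    except Exception as exc:
        raise RuntimeError(f"stage 'detect' failed: {exc}") from exc
    write_fragments_fasta(outdir / "fragments.fa", result.fragments)
    write_hits_tsv(outdir / "hits.tsv", result.hits)
    write_sites_tsv(outdir / "sites.tsv", result.sites)
    write_sites_bed(outdir / "sites.bed", result.sites)
    window_records = []
    for site in result.sites:
        for pw in primer_windows(site, genome):
            for side in ("upstream", "downstream"):
                iv = getattr(pw, side)
                seq = getattr(pw, f"{side}_seq")
                if iv is not None:
                    window_records.append(
                        (f"{site.site_id}|{pw.chromosome}:{iv[0]}-{iv[1]}|{side}", seq)
                    )
    write_fasta(outdir / "primer_windows.fa", window_records)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def run_zygosity(
    sheet: str | Path,
    out_calls: str | Path,
    out_summary: str | Path,
    expected_ratio: tuple[float, float, float] = (2.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Genotype every plant x locus in a sheet and summarise per locus."""
    results = read_genotype_sheet(sheet)
    calls = calls_frame(results)
    by_locus: dict[str, list] = {}
    for r in results:
        by_locus.setdefault(r.locus_id, []).append(r)
    summaries = [
        summarize_segregation(rs, expected_ratio) for _, rs in sorted(by_locus.items())
    ]
    summary = summary_frame(summaries)
    calls.to_csv(out_calls, sep="\t", index=False)
    summary.to_csv(out_summary, sep="\t", index=False)
    return summary
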