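"""Walking-primer motif selection.

Genome-walking primers carry a fixed 6-bp palindromic 3' end that anchors the
primer at restriction-site-like positions genome-wide. A good walking motif
occurs with moderate frequency (enough sites near any insertion to yield an
amplifiable junction, not so many that background amplification dominates)
and with similar density on every chromosome. This module scans a genome for
candidate motifs, summarises their frequency and spatial uniformity, predicts
how many motif-to-motif PCR amplicons of amplifiable size the motif supports,
and ranks a candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from tdnawalk.seqs import is_palindromic


@dataclass(frozen=True)
class MotifProfile:
    """Occurrence profile of one motif over one genome.

    positions are 0-based forward-strand start coordinates, strictly
    increasing within each chromosome; overlapping occurrences are counted.
    """

    motif: str
    positions: dict[str, np.ndarray]
    chromosome_lengths: dict[str, int]

    @property
    def count_per_chromosome(self) -> dict[str, int]:
        return {chrom: int(len(pos)) for chrom, pos in self.positions.items()}

    @property
    def genome_count(self) -> int:
        return sum(self.count_per_chromosome.values())

    @property
    def mean_gap(self) -> dict[str, float | None]:
        """Mean distance between consecutive occurrences, per chromosome and
        genome-wide (key ``*``). Chromosomes with <2 sites contribute None."""
        gaps: dict[str, float | None] = {}
        pooled: list[np.ndarray] = []
        for chrom, pos in self.positions.items():
            if len(pos) >= 2:
                d = np.diff(pos)
                gaps[chrom] = float(d.mean())
                pooled.append(d)
            else:
                gaps[chrom] = None
        gaps["*"] = float(np.concatenate(pooled).mean()) if pooled else None
        return gaps

    @property
    def density_per_mb(self) -> dict[str, float]:
        return {
            chrom: len(self.positions[chrom]) / (self.chromosome_lengths[chrom] / 1e6)
            for chrom in self.positions
        }

    @property
    def density_cv(self) -> float:
        """Coefficient of variation of per-chromosome density (occ/Mb).

        NaN when the motif never occurs (no meaningful uniformity)."""
        dens = np.array(list(self.density_per_mb.values()), dtype=float)
        if dens.size == 0 or dens.mean() == 0:
            return float("nan")
        return float(dens.std() / dens.mean())

    @property
    def genome_density_per_mb(self) -> float:
        total_mb = sum(self.chromosome_lengths.values()) / 1e6
        return self.genome_count / total_mb if total_mb else 0.0


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError(f"motif must be at least 4 bp, got {motif!r}")
    if not set(motif) <= set("ACGT"):
        raise ValueError(f"motif must contain only A/C/G/T, got {motif!r}")
    return motif


def scan_motif(genome: Mapping[str, str], motif: str) -> MotifProfile:
    """Report every exact forward-strand occurrence of ``motif`` in ``genome``.

    Matching is case-insensitive and overlapping occurrences are all
    reported; ambiguous bases (N) never match. For a palindromic motif the
    forward-strand scan covers both strands, since every occurrence is its
    own reverse complement.
    """
    motif = _validate_motif(motif)
    if not genome:
        raise ValueError("genome must contain at least one sequence")
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        lengths[chrom] = len(seq)
        found = []
        start = seq.find(motif)
        while start != -1:
            found.append(start)
            start = seq.find(motif, start + 1)  # +1: overlapping occurrences count
        positions[chrom] = np.asarray(found, dtype=np.int64)
    return MotifProfile(motif=motif, positions=positions, chromosome_lengths=lengths)


def predict_amplicons(
    profile: MotifProfile, min_len: int = 30, max_len: int = 2000
) -> tuple[dict[str, int], int]:
    """Count motif-pair PCR amplicons with size in [min_len, max_len].

    Every ordered pair of occurrences (i < j) on the same chromosome is a
    potential amplicon because the palindromic motif binds the walking primer
    on both strands at every site. The amplicon span is measured from the
    start of the left motif copy to the end of the right copy (both copies
    included). Returns (per-chromosome counts, total).
    """
    if not is_palindromic(profile.motif):
        raise ValueError(
            f"motif {profile.motif!r} is not palindromic; strand-specific "
            "amplicon prediction is unsupported"
        )
    k = len(profile.motif)
    per_chrom: dict[str, int] = {}
    for chrom, pos in profile.positions.items():
        if len(pos) < 2:
            per_chrom[chrom] = 0
            continue
        # span(i, j) = pos[j] + k - pos[i]; count j with span in range for each i
        lo = np.searchsorted(pos, pos + (min_len - k), side="left")
        hi = np.searchsorted(pos, pos + (max_len - k), side="right")
        lo = np.maximum(lo, np.arange(len(pos)) + 1)
        per_chrom[chrom] = int(np.maximum(hi - lo, 0).sum())
    return per_chrom, sum(per_chrom.values())


@dataclass
class MotifRanking:
    motif: str
    rank: int
    in_band: bool
    genome_count: int
    genome_density_per_mb: float
    density_cv: float
    flags: list[str] = field(default_factory=list)


def rank_motifs(
    profiles: Sequence[MotifProfile],
    target_band: tuple[float, float] = (0.5, 1.5),
) -> list[MotifRanking]:
    """Rank candidate motifs for walking-primer design.

    Motifs whose genome-wide density lies inside ``target_band`` (expressed
    relative to the median density of the candidate set) rank above those
    outside; within the band a lower density CV (more uniform across
    chromosomes) ranks higher; ties break lexicographically. Motifs with zero
    occurrences are flagged "unamplifiable" and rank last.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two motif profiles to rank")
    ref_lengths = profiles[0].chromosome_lengths
    for p in profiles[1:]:
        if p.chromosome_lengths != ref_lengths:
            raise ValueError("profiles were computed over different genomes")
    densities = np.array([p.genome_density_per_mb for p in profiles])
    median = float(np.median(densities))
    lo, hi = target_band[0] * median, target_band[1] * median

    def sort_key(p: MotifProfile):
        d = p.genome_density_per_mb
        in_band = (lo <= d <= hi) and p.genome_count > 0
        cv = p.density_cv
        cv_key = cv if np.isfinite(cv) else float("inf")
        # outside the band: order by distance from the band, worst last
        band_dist = 0.0 if in_band else min(abs(d - lo), abs(d - hi))
        return (p.genome_count == 0, not in_band, cv_key if in_band else band_dist, p.motif)

    ordered = sorted(profiles, key=sort_key)
    out = []
    for rank, p in enumerate(ordered, start=1):
        d = p.genome_density_per_mb
        in_band = (lo <= d <= hi) and p.genome_count > 0
        flags = []
        if p.genome_count == 0:
            flags.append("unamplifiable")
        elif not in_band:
            flags.append("outside_band")
        out.append(
            MotifRanking(
                motif=p.motif,
                rank=rank,
                in_band=in_band,
                genome_count=p.genome_count,
                genome_density_per_mb=d,
                density_cv=p.density_cv,
                flags=flags,
            )
        )
    return out


def motif_gc_percent(motif: str) -> float:
    """GC content of a motif in percent, rounded to 2 decimals."""
    motif = _validate_motif(motif)
    return round(100.0 * sum(c in "GC" for c in motif) / len(motif), 2)


def write_motif_report(
    path: str | Path,
    profiles: Sequence[MotifProfile],
    min_len: int = 30,
    max_len: int = 2000,
) -> None:
    """TSV report: motif, chromosome, count, density_per_Mb, mean_gap,
    amplicons_in_range (palindromic motifs only)."""
    with open(path, "w") as out:
        out.write("motif\tchromosome\tcount\tdensity_per_Mb\tmean_gap\tamplicons_in_range\n")
        for p in profiles:
            gaps = p.mean_gap
            amps: dict[str, int] = {}
            if is_palindromic(p.motif):
                amps, _ = predict_amplicons(p, min_len, max_len)
            for chrom in p.positions:
                gap = gaps[chrom]
                out.write(
                    f"{p.motif}\t{chrom}\t{len(p.positions[chrom])}\t"
                    f"{p.density_per_mb[chrom]:.3f}\t"
                    f"{'' if gap is None else f'{gap:.1f}'}\t"
                    f"{amps.get(chrom, '')}\n"
                )


def write_motif_bed(path: str | Path, profile: MotifProfile) -> None:
    """BED (0-based half-open) of motif occurrences."""
    k = len(profile.motif)
    with open(path, "w") as out:
        for chrom, pos in profile.positions.items():
            for p in pos:
                out.write(f"{chrom}\t{p}\t{p + k}\t{profile.motif}\n")
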