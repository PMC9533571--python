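"""Candidate insertion-site calling from genome search hits.

Hits are chained into "hotspots" (regions of accumulated read support) per
chromosome, hotspots sharing supporting fragments across chromosomes are
grouped as homeolog candidates, and each group becomes one candidate site
ranked by a hierarchical list of evidence criteria: detection in both border
libraries within 1 kb first, then the number of satisfied weighting flags
(multiple PCR libraries; e-value < 1e-30 or identity > 99%; a supporting
read over 60 bp), then raw read support. Orientation of the integrated T-DNA
is inferred from the strand of each hit combined with its read of origin,
and primer windows 250-500 bp either side of the insertion point are emitted
for verification-primer design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from tdnawalk.genome_search import GenomeHit


@dataclass
class Hotspot:
    """A chained cluster of hits on one chromosome."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    hits: list[GenomeHit]

    @property
    def n_reads(self) -> int:
        return len(self.hits)

    @property
    def border_counts(self) -> dict[str, int]:
        counts = {"LB": 0, "RB": 0}
        for h in self.hits:
            if h.border in counts:
                counts[h.border] += 1
        return counts

    @property
    def libraries(self) -> set[str]:
        return {h.walking_primer_id for h in self.hits if h.walking_primer_id}

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.hits)

    @property
    def best_identity(self) -> float:
        return max(h.pident for h in self.hits)

    @property
    def max_supporting_read_len(self) -> int:
        return max(h.qlen for h in self.hits)

    @property
    def mean_identity(self) -> float:
        return float(np.mean([h.pident for h in self.hits]))

    @property
    def fragment_ids(self) -> set[str]:
        return {h.fragment_id for h in self.hits}

    def border_interval(self, border: str) -> Optional[tuple[int, int]]:
        pos = [(h.s_lo, h.s_hi) for h in self.hits if h.border == border]
        if not pos:
            return None
        return min(p[0] for p in pos), max(p[1] for p in pos)


def cluster_hits(hits: Sequence[GenomeHit], gap: int = 1000) -> list[Hotspot]:
    """Single-linkage chaining of hits per chromosome.

    Hits are sorted by start position within each chromosome; a new hotspot
    opens whenever the next start is more than ``gap`` beyond the previous
    start. Strands and borders are pooled. Idempotent under re-clustering.
    """
    by_chrom: dict[str, list[GenomeHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chromosome, []).append(h)
    hotspots: list[Hotspot] = []
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: (h.s_lo, h.s_hi))
        current: list[GenomeHit] = []
        prev_start = None
        for h in chrom_hits:
            if prev_start is not None and h.s_lo - prev_start > gap:
                hotspots.append(_make_hotspot(chrom, current))
                current = []
            current.append(h)
            prev_start = h.s_lo
        if current:
            hotspots.append(_make_hotspot(chrom, current))
    hotspots.sort(key=lambda hs: (hs.chromosome, hs.start))
    return hotspots


def _make_hotspot(chrom: str, hits: list[GenomeHit]) -> Hotspot:
    return Hotspot(
        chromosome=chrom,
        start=min(h.s_lo for h in hits),
        end=max(h.s_hi for h in hits),
        hits=hits,
    )


@dataclass(frozen=True)
class HomeologEvidence:
    """Per-homeolog-candidate evidence used for disambiguation: the mean
    identity of supporting hits and the number of fragments for which this
    candidate is the strictly best placement genome-wide."""

    chromosome: str
    mean_identity: float
    top_support: int


@dataclass
class HomeologStatus:
    resolved: bool
    chromosomes: list[str]  # single element when resolved, all members on tie

    def __str__(self) -> str:
        label = "resolved" if self.resolved else "tie"
        return f"{label}({','.join(self.chromosomes)})"


def resolve_homeologs(
    members: Sequence[HomeologEvidence],
    identity_margin: float = 0.5,
    support_ratio: float = 2.0,
) -> HomeologStatus:
    """Decide whether one homeolog candidate clearly carries the insertion.

    The leader must beat every other member by more than ``identity_margin``
    percentage points of mean identity AND hold at least ``support_ratio``
    times the runner-up's top-placement support; otherwise all members are
    kept as a tie (the conservative outcome when homeologs are effectively
    indistinguishable, e.g. at zero divergence).
    """
    if not members:
        raise ValueError("empty homeolog group")
    if len(members) == 1:
        return HomeologStatus(True, [members[0].chromosome])
    ranked = sorted(members, key=lambda m: (-m.mean_identity, -m.top_support, m.chromosome))
    leader, rest = ranked[0], ranked[1:]
    identity_ok = all(leader.mean_identity > m.mean_identity + identity_margin for m in rest)
    runner_support = max(m.top_support for m in rest)
    support_ok = leader.top_support >= max(1, support_ratio * runner_support)
    if identity_ok and support_ok:
        return HomeologStatus(True, [leader.chromosome])
    return HomeologStatus(False, sorted(m.chromosome for m in members))


@dataclass
class CandidateSite:
    site_id: str
    hotspots: list[Hotspot]
    flags: dict[str, bool]
    homeolog_status: HomeologStatus
    orientation: str = "undetermined"
    transgene_id: str = ""
    rank: int = 0

    @property
    def primary(self) -> Hotspot:
        """The best-supported member hotspot."""
        return max(self.hotspots, key=lambda hs: (hs.n_reads, -hs.best_evalue))

    @property
    def n_reads(self) -> int:
        return sum(hs.n_reads for hs in self.hotspots)

    @property
    def n_flags(self) -> int:
        return sum(self.flags.values())

    @property
    def best_evalue(self) -> float:
        return min(hs.best_evalue for hs in self.hotspots)

    @property
    def best_identity(self) -> float:
        return max(hs.best_identity for hs in self.hotspots)


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] < b[0]:
        return b[0] - a[1]
    if b[1] < a[0]:
        return a[0] - b[1]
    return 0


def _both_borders(hotspot: Hotspot, gap: int) -> bool:
    lb = hotspot.border_interval("LB")
    rb = hotspot.border_interval("RB")
    return lb is not None and rb is not None and _interval_distance(lb, rb) <= gap


def _group_homeologs(hotspots: Sequence[Hotspot], min_shared: float = 0.5) -> list[list[Hotspot]]:
    """Connected components of hotspots sharing >= min_shared of the smaller
    member's supporting fragment IDs (homeolog triplets in an allohexaploid)."""
    n = len(hotspots)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    frag_sets = [hs.fragment_ids for hs in hotspots]
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(frag_sets[i] & frag_sets[j])
            if shared and shared >= min_shared * min(len(frag_sets[i]), len(frag_sets[j])):
                parent[find(i)] = find(j)
    groups: dict[int, list[Hotspot]] = {}
    for i, hs in enumerate(hotspots):
        groups.setdefault(find(i), []).append(hs)
    return [sorted(g, key=lambda hs: (hs.chromosome, hs.start)) for g in groups.values()]


def _top_support(group: Sequence[Hotspot]) -> dict[int, int]:
    """Per member: number of fragments whose strictly best (lowest e-value)
    hit within the group lies on that member."""
    best: dict[str, tuple[float, int, bool]] = {}  # frag -> (best evalue, member, unique)
    for mi, hs in enumerate(group):
        for h in hs.hits:
            cur = best.get(h.fragment_id)
            if cur is None or h.evalue < cur[0]:
                best[h.fragment_id] = (h.evalue, mi, True)
            elif h.evalue == cur[0] and cur[1] != mi:
                best[h.fragment_id] = (cur[0], cur[1], False)
    support = {mi: 0 for mi in range(len(group))}
    for _, mi, unique in best.values():
        if unique:
            support[mi] += 1
    return support


def flag_and_rank(
    hotspots: Sequence[Hotspot],
    other_lines: Sequence[Sequence[Hotspot]] = (),
    gap: int = 1000,
    strong_evalue: float = 1e-30,
    strong_identity: float = 99.0,
    long_read_len: int = 60,
    pooled_counts_as_library: bool = True,
    identity_margin: float = 0.5,
    support_ratio: float = 2.0,
) -> list[CandidateSite]:
    """Turn one line's hotspots into ranked candidate sites.

    Flags: both_borders (LB and RB support within ``gap``), multi_library
    (more than one walking-primer library), strong_stats (best e-value below
    ``strong_evalue`` or best identity above ``strong_identity``), long_read
    (a supporting read of at least ``long_read_len`` bp), line_unique (no
    hotspot within ``gap`` in any other line). Rank is the lexicographic
    order (both_borders, number of true flags, total read support, best
    e-value), with coordinates as the deterministic tie-break.
    """
    sites: list[CandidateSite] = []
    for gi, group in enumerate(_group_homeologs(hotspots)):
        support = _top_support(group)
        evidence = [
            HomeologEvidence(hs.chromosome, hs.mean_identity, support[mi])
            for mi, hs in enumerate(group)
        ]
        status = resolve_homeologs(evidence, identity_margin, support_ratio)
        libraries: set[str] = set()
        for hs in group:
            libraries |= hs.libraries
        if not pooled_counts_as_library:
            libraries.discard("pooled")
        flags = {
            "both_borders": any(_both_borders(hs, gap) for hs in group),
            "multi_library": len(libraries) > 1,
            "strong_stats": any(
                hs.best_evalue < strong_evalue or hs.best_identity > strong_identity
                for hs in group
            ),
            "long_read": any(hs.max_supporting_read_len >= long_read_len for hs in group),
            "line_unique": not any(
                hs.chromosome == other.chromosome
                and _interval_distance((hs.start, hs.end), (other.start, other.end)) <= gap
                for hs in group
                for line in other_lines
                for other in line
            ),
        }
        transgenes = [h.vector_id for hs in group for h in hs.hits if h.vector_id]
        transgene_id = max(set(transgenes), key=transgenes.count) if transgenes else ""
        site = CandidateSite(
            site_id=f"site_{gi + 1}",
            hotspots=list(group),
            flags=flags,
            homeolog_status=status,
            transgene_id=transgene_id,
        )
        site.orientation = infer_orientation(site)
        sites.append(site)
    sites.sort(
        key=lambda s: (
            not s.flags["both_borders"],
            -s.n_flags,
            -s.n_reads,
            s.best_evalue,
            s.primary.chromosome,
            s.primary.start,
        )
    )
    for rank, site in enumerate(sites, start=1):
        site.rank = rank
        site.site_id = f"site_{rank}"
    return sites


def _orientation_vote(border: str, which_read: int, strand: str) -> Optional[str]:
    """One hit's vote for the T-DNA configuration on the + strand.

    Read 2 runs from the transgene outward into the genome, read 1 from the
    walking primer back toward it, so within one border library the two reads
    vote on opposite strands. A left-border read 2 matching the + strand
    means the LB-adjacent flank extends to the right of the T-DNA, i.e. the
    cassette reads RB->LB along the + strand (RB-LB), and mirrored for the
    right border.
    """
    if which_read not in (1, 2) or strand not in ("+", "-") or border not in ("LB", "RB"):
        return None
    outward_plus = (which_read == 2) == (strand == "+")  # amplicon walks rightward
    if border == "LB":
        return "RB-LB" if outward_plus else "LB-RB"
    return "LB-RB" if outward_plus else "RB-LB"


def infer_orientation(
    site: CandidateSite | Sequence[GenomeHit],
    quorum: float = 0.8,
) -> str:
    """Call RB-LB / LB-RB from hit strands and reads of origin.

    The call is made only when at least ``quorum`` of informative hits agree;
    conflicting or absent evidence yields "undetermined".
    """
    if isinstance(site, CandidateSite):
        hits: Iterable[GenomeHit] = [h for hs in site.hotspots for h in hs.hits]
    else:
        hits = site
    votes = {"RB-LB": 0, "LB-RB": 0}
    for h in hits:
        v = _orientation_vote(h.border, h.which_read, h.strand)
        if v is not None:
            votes[v] += 1
    total = votes["RB-LB"] + votes["LB-RB"]
    if total == 0:
        return "undetermined"
    for orientation, count in votes.items():
        if count / total >= quorum:
            return orientation
    return "undetermined"


def estimate_insertion_point(hotspot: Hotspot, gap: int = 1000) -> int:
    """Estimate the junction coordinate (1-based) within a hotspot.

    With both borders present the junction lies between the two border
    support intervals: the midpoint of the gap (or overlap) between their
    facing edges. With one border, junction-spanning clips start at the
    junction and walking-end reads lie farther out, so the interval edge on
    the T-DNA side — indicated by the hit strands — is used; if the walking
    direction is unclear the interval midpoint is returned.
    """
    lb = hotspot.border_interval("LB")
    rb = hotspot.border_interval("RB")
    if lb is not None and rb is not None:
        if lb[1] < rb[0]:
            return (lb[1] + rb[0]) // 2
        if rb[1] < lb[0]:
            return (rb[1] + lb[0]) // 2
        lo, hi = max(lb[0], rb[0]), min(lb[1], rb[1])
        return (lo + hi) // 2
    rightward = 0
    leftward = 0
    for h in hotspot.hits:
        if h.which_read == 2:
            rightward += h.strand == "+"
            leftward += h.strand == "-"
        elif h.which_read == 1:
            rightward += h.strand == "-"
            leftward += h.strand == "+"
    if rightward > leftward:
        return hotspot.start  # flank extends right; T-DNA borders the left edge
    if leftward > rightward:
        return hotspot.end
    return (hotspot.start + hotspot.end) // 2


@dataclass
class PrimerWindows:
    chromosome: str
    insertion_point: int  # 1-based
    upstream: Optional[tuple[int, int]]  # 1-based inclusive
    downstream: Optional[tuple[int, int]]
    upstream_seq: Optional[str]
    downstream_seq: Optional[str]
    warnings: list[str] = field(default_factory=list)


def primer_windows(
    site: CandidateSite,
    genome: Mapping[str, str],
    flank: tuple[int, int] = (250, 500),
    gap: int = 1000,
) -> list[PrimerWindows]:
    """Genomic windows ``flank`` bp either side of the insertion point, for
    external primer design (one window set per homeolog tie member).

    Windows are clipped at chromosome ends; a window that vanishes entirely
    produces a one-sided result with a warning.
    """
    min_f, max_f = flank
    if not (0 < min_f < max_f):
        raise ValueError("flank must be an increasing positive range")
    out: list[PrimerWindows] = []
    for chrom in site.homeolog_status.chromosomes:
        hotspot = next(hs for hs in site.hotspots if hs.chromosome == chrom)
        point = estimate_insertion_point(hotspot, gap)
        chrom_len = len(genome[chrom])
        warnings: list[str] = []
        up: Optional[tuple[int, int]] = (point - max_f, point - min_f)
        if up[1] < 1:
            up = None
            warnings.append(f"upstream window absent: insertion point {point} within {min_f} bp of chromosome start")
        elif up[0] < 1:
            up = (1, up[1])
            warnings.append("upstream window clipped at chromosome start")
        down: Optional[tuple[int, int]] = (point + min_f, point + max_f)
        if down[0] > chrom_len:
            down = None
            warnings.append(f"downstream window absent: insertion point {point} within {min_f} bp of chromosome end")
        elif down[1] > chrom_len:
            down = (down[0], chrom_len)
            warnings.append("downstream window clipped at chromosome end")
        out.append(
            PrimerWindows(
                chromosome=chrom,
                insertion_point=point,
                upstream=up,
                downstream=down,
                upstream_seq=genome[chrom][up[0] - 1 : up[1]] if up else None,
                downstream_seq=genome[chrom][down[0] - 1 : down[1]] if down else None,
                warnings=warnings,
            )
        )
    return out


def write_sites_tsv(path: str | Path, sites: Sequence[CandidateSite]) -> None:
    """Candidate-site report (coordinates 1-based inclusive)."""
    with open(path, "w") as out:
        out.write(
            "# coordinates: 1-based inclusive\n"
            "site_id\trank\tchromosomes\tinterval\tboth_borders\tmulti_library\t"
            "strong_stats\tlong_read\tline_unique\treads_LB\treads_RB\tlibraries\t"
            "best_evalue\tbest_identity\torientation\thomeolog_status\ttransgene_id\n"
        )
        for s in sites:
            primary = s.primary
            borders = {"LB": 0, "RB": 0}
            libs: set[str] = set()
            for hs in s.hotspots:
                bc = hs.border_counts
                borders["LB"] += bc["LB"]
                borders["RB"] += bc["RB"]
                libs |= hs.libraries
            out.write(
                f"{s.site_id}\t{s.rank}\t{','.join(hs.chromosome for hs in s.hotspots)}\t"
                f"{primary.chromosome}:{primary.start}-{primary.end}\t"
                f"{s.flags['both_borders']}\t{s.flags['multi_library']}\t"
                f"{s.flags['strong_stats']}\t{s.flags['long_read']}\t{s.flags['line_unique']}\t"
                f"{borders['LB']}\t{borders['RB']}\t{','.join(sorted(libs))}\t"
                f"{s.best_evalue:.3g}\t{s.best_identity:.2f}\t{s.orientation}\t"
                f"{s.homeolog_status}\t{s.transgene_id}\n"
            )


def write_sites_bed(path: str | Path, sites: Sequence[CandidateSite]) -> None:
    """BED (0-based half-open) of candidate-site member hotspots."""
    with open(path, "w") as out:
        for s in sites:
            for hs in s.hotspots:
                out.write(f"{hs.chromosome}\t{hs.start - 1}\t{hs.end}\t{s.site_id}\t{s.rank}\n")
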