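"""Ground-truthed simulation of walking-PCR insertion-site libraries.

The simulator emulates the full experimental system: an allopolyploid genome
built from near-identical homeologous subgenomes, T-DNA cassettes spliced in
with configurable orientation and border truncation, and the two-phase
walking-PCR amplicon library — each amplicon runs from a nested border
primer inside the T-DNA across the junction to a palindromic walking-motif
site in the flanking genome, carries 10 primer-derived degenerate bases at
the walking end, and is size-selected to 150-1200 bp. Paired 150 bp reads
are emitted with read 2 at the transgene end and read 1 at the walking end,
with substitution sequencing error, exact PCR duplicates, and background
motif-to-motif mispriming amplicons at configurable rates. A companion
routine simulates Mendelian (or deliberately non-Mendelian) T2 segregation
with the corresponding two-PCR genotype sheet.

Everything is bit-reproducible given a configuration and seed, and every
read name carries its truth amplicon ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from tdnawalk.motifs import scan_motif
from tdnawalk.seqs import revcomp, write_fasta, write_fastq
from tdnawalk.vector_trim import LibraryMeta, ReadPair

# canonical nopaline-type border repeats (25 bp each)
LEFT_BORDER_REPEAT = "TGGCAGGATATATTGTGGTGTAAAC"
RIGHT_BORDER_REPEAT = "TGACAGGATATATTGGCGGGTAAAC"

DEFAULT_WALKING_MOTIFS = ("GTTAAC", "CCATGG", "CTCGAG", "GTCGAC")

# TruSeq-style adapter read-through sequences (read 1 / read 2 side)
ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class InsertionSpec:
    construct_id: str
    chromosome: str
    position: int  # 1-based: T-DNA is spliced between position and position+1
    orientation: str = "LB-RB"  # cassette direction read along the + strand
    lb_truncation: int = 0  # bp removed from the LB end of the cassette
    rb_truncation: int = 0

    def __post_init__(self):
        if self.orientation not in ("LB-RB", "RB-LB"):
            raise ValueError(f"orientation must be LB-RB or RB-LB, got {self.orientation!r}")


@dataclass
class InsertionTruth:
    construct_id: str
    chromosome: str
    position: int  # 1-based coordinate of the last genomic base before the insert (post-insertion)
    ref_position: int  # same junction on the pre-insertion reference genome
    orientation: str
    lb_truncation: int
    rb_truncation: int
    insert_length: int
    left_flank: str  # up to 1 kb of pre-insertion genome on each side
    right_flank: str
    amplicons_per_border: dict[str, int] = field(default_factory=lambda: {"LB": 0, "RB": 0})

    @property
    def right_junction(self) -> int:
        """1-based coordinate of the first genomic base after the insert."""
        return self.position + self.insert_length + 1

    @property
    def detectable(self) -> bool:
        return any(n > 0 for n in self.amplicons_per_border.values())


@dataclass
class SimulationConfig:
    seed: int = 17
    line_id: str = "line1"
    n_subgenomes: int = 3
    chromosomes_per_subgenome: int = 3
    chromosome_length: int = 500_000
    homeolog_divergence: float = 0.02
    n_constructs: int = 2
    construct_length: int = 4000
    n_insertions: int = 5
    insertions: Optional[list[InsertionSpec]] = None  # explicit specs override n_insertions
    walking_motifs: tuple[str, ...] = DEFAULT_WALKING_MOTIFS
    amplicon_depth: int = 100
    read_length: int = 150
    error_rate: float = 0.003
    duplicate_rate: float = 0.10
    background_fraction: float = 0.05
    dimer_rate: float = 0.0
    size_min: int = 150
    size_max: int = 1200
    border_primer_offset: int = 100  # nested primer distance from the border repeat
    degenerate_len: int = 10  # primer-derived random bases at the walking end
    include_pooled: bool = True
    primer_efficiency: Optional[dict[str, float]] = None  # motif -> multiplier
    adapter_r1: str = ADAPTER_R1
    adapter_r2: str = ADAPTER_R2

    def __post_init__(self):
        for rate in (self.homeolog_divergence, self.error_rate, self.duplicate_rate,
                     self.background_fraction, self.dimer_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.homeolog_divergence >= 0.2:
            raise ValueError("homeolog divergence must be < 0.2")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-base substitutions at the given rate."""
    if rate <= 0 or not seq:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.full(codes.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        base_idx[codes == b] = i
    hit = (rng.random(len(codes)) < rate) & (base_idx >= 0)
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes[hit] = _BASES[(base_idx[hit] + shift) % 4]
    return codes.tobytes().decode("ascii")


def make_polyploid_genome(
    cfg: SimulationConfig, seed=None
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Build an allopolyploid genome: one random ancestral sequence per
    chromosome, copied into each subgenome with independent substitutions at
    the homeolog divergence rate. Substitution-only divergence keeps
    orthologous coordinates identical across subgenomes, so the homeolog map
    is simply the name grouping."""
    rng = _rng(cfg.seed if seed is None else seed)
    genome: dict[str, str] = {}
    homeolog_map: dict[str, list[str]] = {}
    for c in range(cfg.chromosomes_per_subgenome):
        ancestral = _random_dna(rng, cfg.chromosome_length)
        names = []
        for s in range(cfg.n_subgenomes):
            name = f"chr{c + 1}{chr(ord('A') + s)}"
            genome[name] = _mutate(rng, ancestral, cfg.homeolog_divergence)
            names.append(name)
        homeolog_map[f"chr{c + 1}"] = names
    return genome, homeolog_map


def make_construct(rng_or_seed, construct_id: str, length: int = 4000) -> str:
    """A T-DNA cassette: LB repeat + random payload + RB repeat, recorded
    LB->RB (5'->3')."""
    rng = _rng(rng_or_seed)
    payload = _random_dna(rng, length - len(LEFT_BORDER_REPEAT) - len(RIGHT_BORDER_REPEAT))
    return LEFT_BORDER_REPEAT + payload + RIGHT_BORDER_REPEAT


def insert_constructs(
    genome: Mapping[str, str],
    constructs: Mapping[str, str],
    specs: Sequence[InsertionSpec],
    flank_len: int = 1000,
) -> tuple[dict[str, str], list[InsertionTruth]]:
    """Splice cassettes into the genome and emit truth records in
    post-insertion coordinates. Border truncations remove border-proximal
    cassette sequence before splicing; RB-LB insertions splice the reverse
    complement. Insertions at the same point are rejected."""
    by_chrom: dict[str, list[InsertionSpec]] = {}
    for spec in specs:
        if spec.chromosome not in genome:
            raise ValueError(f"unknown chromosome {spec.chromosome!r}")
        if not 1 <= spec.position < len(genome[spec.chromosome]):
            raise ValueError(f"insertion position {spec.position} outside {spec.chromosome}")
        by_chrom.setdefault(spec.chromosome, []).append(spec)
    modified = dict(genome)
    truths: list[InsertionTruth] = []
    for chrom, chrom_specs in by_chrom.items():
        chrom_specs.sort(key=lambda s: s.position)
        positions = [s.position for s in chrom_specs]
        if len(set(positions)) != len(positions):
            raise ValueError(f"overlapping insertions on {chrom}")
        seq = genome[chrom]
        parts: list[str] = []
        cursor = 0
        offset = 0
        for spec in chrom_specs:
            cassette = constructs[spec.construct_id]
            if spec.lb_truncation + spec.rb_truncation >= len(cassette):
                raise ValueError(f"truncations consume the whole cassette {spec.construct_id}")
            insert = cassette[spec.lb_truncation : len(cassette) - spec.rb_truncation]
            if spec.orientation == "RB-LB":
                insert = revcomp(insert)
            parts.append(seq[cursor : spec.position])
            parts.append(insert)
            cursor = spec.position
            truths.append(
                InsertionTruth(
                    construct_id=spec.construct_id,
                    chromosome=chrom,
                    position=spec.position + offset,
                    ref_position=spec.position,
                    orientation=spec.orientation,
                    lb_truncation=spec.lb_truncation,
                    rb_truncation=spec.rb_truncation,
                    insert_length=len(insert),
                    left_flank=seq[max(0, spec.position - flank_len) : spec.position],
                    right_flank=seq[spec.position : spec.position + flank_len],
                )
            )
            offset += len(insert)
        parts.append(seq[cursor:])
        modified[chrom] = "".join(parts)
    truths.sort(key=lambda t: (t.chromosome, t.position))
    return modified, truths


@dataclass
class AmpliconTruth:
    amp_id: str
    line_id: str
    border: str
    walking_primer_id: str
    motif: str
    chromosome: str
    junction: int  # 1-based genomic coordinate of the junction (truth position)
    motif_position: int  # 0-based start of the anchoring motif occurrence
    length: int  # insert length incl. degenerate bases
    construct_id: str
    truth_index: int  # -1 for background amplicons
    walking_strand_seq: str  # amplicon as read by read 1 (walking end first)


@dataclass
class LibrarySimulation:
    read_pairs: list[ReadPair]
    amplicons: list[AmpliconTruth]
    truths: list[InsertionTruth]
    n_signal_pairs: int = 0
    n_background_pairs: int = 0
    n_duplicate_pairs: int = 0


def _border_geometry(truth: InsertionTruth) -> dict[str, tuple[str, int]]:
    """Which border sits at which junction, given the insertion orientation.

    Returns border -> (walk direction, effective primer offset source):
    direction "left" means the amplicon extends into the genome below the
    insertion point, "right" above it.
    """
    if truth.orientation == "LB-RB":
        return {"LB": ("left", truth.lb_truncation), "RB": ("right", truth.rb_truncation)}
    return {"RB": ("left", truth.rb_truncation), "LB": ("right", truth.lb_truncation)}


def _make_read_pair(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    walking_strand: str,
    pair_id: str,
    meta: LibraryMeta,
) -> ReadPair:
    """Paired reads from one amplicon molecule: read 1 from the walking end,
    read 2 from the transgene end; inserts shorter than the read length run
    through into the adapter."""
    L = cfg.read_length
    r1_template = walking_strand + cfg.adapter_r1 * 3
    r2_template = revcomp(walking_strand) + cfg.adapter_r2 * 3
    read1 = _mutate(rng, r1_template[:L], cfg.error_rate)
    read2 = _mutate(rng, r2_template[:L], cfg.error_rate)
    qual = "?" * L  # constant Q30
    return ReadPair(id=pair_id, read1_seq=read1, read2_seq=read2, library=meta,
                    read1_qual=qual, read2_qual=qual)


def simulate_library(
    modified_genome: Mapping[str, str],
    truths: Sequence[InsertionTruth],
    cfg: SimulationConfig,
    seed=None,
) -> LibrarySimulation:
    """Emit the paired-read walking-PCR library for a set of insertions.

    For every insertion and border, amplicons run from the nested border
    primer (``border_primer_offset`` bp inside the T-DNA, less any border
    truncation) across the junction to each walking-motif occurrence whose
    resulting insert length falls within the size-selection window. A border
    whose primer site was truncated away, or with no in-range motif, yields
    zero amplicons — the undetectable-insertion scenario.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    motif_positions = {
        motif: scan_motif(modified_genome, motif).positions for motif in cfg.walking_motifs
    }
    efficiency = cfg.primer_efficiency or {}
    amplicons: list[AmpliconTruth] = []
    truths = [replace(t, amplicons_per_border={"LB": 0, "RB": 0}) for t in truths]
    deg = cfg.degenerate_len
    for ti, truth in enumerate(truths):
        chrom_seq = modified_genome[truth.chromosome]
        left_j = truth.position  # 0-based index of first insert base
        right_j = truth.position + truth.insert_length  # 0-based index just past insert
        for border, (direction, truncation) in _border_geometry(truth).items():
            o_eff = cfg.border_primer_offset - truncation
            if o_eff < 30:  # primer site truncated away
                continue
            for mi, motif in enumerate(cfg.walking_motifs):
                pos = motif_positions[motif][truth.chromosome]
                k = len(motif)
                if direction == "left":
                    # motif in the left flank; amplicon = motif..junction..primer
                    lo = left_j - (cfg.size_max - deg - o_eff)
                    cand = pos[(pos >= lo) & (pos + k <= left_j)]
                    for m in cand:
                        length = deg + (left_j + o_eff - int(m))
                        if not cfg.size_min <= length <= cfg.size_max:
                            continue
                        walking = (
                            _random_dna(rng, deg) + chrom_seq[int(m) : left_j + o_eff]
                        )
                        amplicons.append(
                            AmpliconTruth(
                                amp_id=f"t{ti}.{border}.{motif}.{int(m)}",
                                line_id=cfg.line_id,
                                border=border,
                                walking_primer_id=f"PST{mi + 1}",
                                motif=motif,
                                chromosome=truth.chromosome,
                                junction=truth.position,
                                motif_position=int(m),
                                length=length,
                                construct_id=truth.construct_id,
                                truth_index=ti,
                                walking_strand_seq=walking,
                            )
                        )
                        truth.amplicons_per_border[border] += 1
                else:
                    hi = right_j + (cfg.size_max - deg - o_eff)
                    cand = pos[(pos >= right_j) & (pos + k <= hi)]
                    for m in cand:
                        length = deg + (int(m) + k - (right_j - o_eff))
                        if not cfg.size_min <= length <= cfg.size_max:
                            continue
                        walking = _random_dna(rng, deg) + revcomp(
                            chrom_seq[right_j - o_eff : int(m) + k]
                        )
                        amplicons.append(
                            AmpliconTruth(
                                amp_id=f"t{ti}.{border}.{motif}.{int(m)}",
                                line_id=cfg.line_id,
                                border=border,
                                walking_primer_id=f"PST{mi + 1}",
                                motif=motif,
                                chromosome=truth.chromosome,
                                junction=truth.right_junction,
                                motif_position=int(m),
                                length=length,
                                construct_id=truth.construct_id,
                                truth_index=ti,
                                walking_strand_seq=walking,
                            )
                        )
                        truth.amplicons_per_border[border] += 1

    pairs: list[ReadPair] = []
    n_signal = 0
    for amp in amplicons:
        eff = efficiency.get(amp.motif, 1.0)
        copies = max(0, int(round(cfg.amplicon_depth * eff)))
        metas = [(amp.walking_primer_id, copies)]
        if cfg.include_pooled:
            metas.append(("pooled", max(1, copies // max(1, len(cfg.walking_motifs)))))
        for primer_id, n in metas:
            meta = LibraryMeta(cfg.line_id, amp.border, primer_id)
            for c in range(n):
                pairs.append(
                    _make_read_pair(rng, cfg, amp.walking_strand_seq,
                                    f"{amp.amp_id}.{primer_id}.{c}", meta)
                )
                n_signal += 1

    # background: walking-primer mispriming between two motif sites
    n_background = int(round(cfg.background_fraction * n_signal))
    chroms = list(modified_genome)
    made = 0
    attempts = 0
    while made < n_background and attempts < n_background * 20:
        attempts += 1
        mi = int(rng.integers(0, len(cfg.walking_motifs)))
        motif = cfg.walking_motifs[mi]
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = motif_positions[motif][chrom]
        if len(pos) < 2:
            continue
        i = int(rng.integers(0, len(pos) - 1))
        lo = np.searchsorted(pos, pos[i] + (cfg.size_min - deg) - len(motif))
        hi = np.searchsorted(pos, pos[i] + (cfg.size_max - deg) - len(motif), side="right")
        lo = max(lo, i + 1)
        if hi <= lo:
            continue
        j = int(rng.integers(lo, hi))
        seg = modified_genome[chrom][int(pos[i]) : int(pos[j]) + len(motif)]
        walking = _random_dna(rng, deg) + seg
        border = "LB" if rng.random() < 0.5 else "RB"
        meta = LibraryMeta(cfg.line_id, border, f"PST{mi + 1}")
        amp = AmpliconTruth(
            amp_id=f"bg{made}.{motif}.{chrom}.{int(pos[i])}",
            line_id=cfg.line_id,
            border=border,
            walking_primer_id=meta.walking_primer_id,
            motif=motif,
            chromosome=chrom,
            junction=0,
            motif_position=int(pos[i]),
            length=deg + len(seg),
            construct_id="",
            truth_index=-1,
            walking_strand_seq=walking,
        )
        amplicons.append(amp)
        pairs.append(_make_read_pair(rng, cfg, walking, f"{amp.amp_id}.0", meta))
        made += 1

    # adapter dimers (wildtype-library artefact; off by default)
    n_dimers = int(round(cfg.dimer_rate * n_signal))
    for d in range(n_dimers):
        meta = LibraryMeta(cfg.line_id, "LB" if rng.random() < 0.5 else "RB", "PST1")
        pairs.append(_make_read_pair(rng, cfg, "", f"dimer{d}", meta))

    # exact PCR duplicates of already-emitted pairs
    dup_mask = rng.random(len(pairs)) < cfg.duplicate_rate
    duplicates = [
        ReadPair(id=f"{p.id}.dup", read1_seq=p.read1_seq, read2_seq=p.read2_seq,
                 library=p.library, read1_qual=p.read1_qual, read2_qual=p.read2_qual)
        for p, d in zip(list(pairs), dup_mask) if d
    ]
    pairs.extend(duplicates)
    return LibrarySimulation(
        read_pairs=pairs,
        amplicons=amplicons,
        truths=list(truths),
        n_signal_pairs=n_signal,
        n_background_pairs=made,
        n_duplicate_pairs=len(duplicates),
    )


def simulate_t2(
    locus_ids: Sequence[str],
    n_plants: int,
    seed=None,
    homozygous_lethal: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate T2 selfed progeny of a plant hemizygous at each locus.

    Each locus segregates independently at 1/2 het : 1/4 hmz : 1/4 null.
    Loci listed in ``homozygous_lethal`` lose their homozygotes before
    sampling (2:0:1 among survivors). Returns (genotype sheet with PCR A/B
    outcomes, true genotypes), both as DataFrames.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    rng = _rng(seed)
    lethal = set(homozygous_lethal)
    genotype_to_pcr = {"het": ("+", "+"), "hmz": ("+", "-"), "null": ("-", "+")}
    sheet_rows, truth_rows = [], []
    for plant in range(1, n_plants + 1):
        for locus in locus_ids:
            if locus in lethal:
                g = rng.choice(["het", "null"], p=[2 / 3, 1 / 3])
            else:
                g = rng.choice(["het", "hmz", "null"], p=[0.5, 0.25, 0.25])
            a, b = genotype_to_pcr[g]
            sheet_rows.append(
                {"plant_id": f"plant{plant}", "locus_id": locus, "pcrA": a, "pcrB": b}
            )
            truth_rows.append({"plant_id": f"plant{plant}", "locus_id": locus, "genotype": g})
    return pd.DataFrame(sheet_rows), pd.DataFrame(truth_rows)


@dataclass
class SimulatedDataset:
    cfg: SimulationConfig
    genome: dict[str, str]  # pre-insertion reference (search target)
    homeolog_map: dict[str, list[str]]
    constructs: dict[str, str]
    modified_genome: dict[str, str]
    truths: list[InsertionTruth]
    library: LibrarySimulation


def simulate_dataset(cfg: SimulationConfig, seed=None) -> SimulatedDataset:
    """One full ground-truthed dataset: polyploid reference, cassettes,
    insertions (explicit specs or random placement), and the read library.

    Random insertions are placed at least 2 kb from chromosome ends and 5 kb
    apart, on randomly chosen chromosomes, with random orientation and
    constructs assigned round-robin.
    """
    master = _rng(cfg.seed if seed is None else seed)
    genome, homeolog_map = make_polyploid_genome(cfg, master)
    constructs = {
        f"construct{k + 1}": make_construct(master, f"construct{k + 1}", cfg.construct_length)
        for k in range(cfg.n_constructs)
    }
    specs = cfg.insertions
    if specs is None:
        specs = []
        margin = 2000
        used: dict[str, list[int]] = {}
        chrom_names = list(genome)
        construct_ids = list(constructs)
        tries = 0
        while len(specs) < cfg.n_insertions and tries < cfg.n_insertions * 100:
            tries += 1
            chrom = chrom_names[int(master.integers(0, len(chrom_names)))]
            pos = int(master.integers(margin, len(genome[chrom]) - margin))
            if any(abs(pos - p) < 5000 for p in used.get(chrom, [])):
                continue
            used.setdefault(chrom, []).append(pos)
            specs.append(
                InsertionSpec(
                    construct_id=construct_ids[len(specs) % len(construct_ids)],
                    chromosome=chrom,
                    position=pos,
                    orientation="LB-RB" if master.random() < 0.5 else "RB-LB",
                )
            )
    modified, truths = insert_constructs(genome, constructs, specs)
    library = simulate_library(modified, truths, cfg, master)
    return SimulatedDataset(
        cfg=cfg,
        genome=genome,
        homeolog_map=homeolog_map,
        constructs=constructs,
        modified_genome=modified,
        truths=library.truths,
        library=library,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write genome FASTA, construct FASTA, paired FASTQ (gzipped), library
    sheet TSV and truth TSV for external use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", dataset.genome)
    write_fasta(outdir / "constructs.fa", dataset.constructs)
    write_fastq(
        outdir / "reads_R1.fastq.gz",
        ((p.id, p.read1_seq, p.read1_qual or "?" * len(p.read1_seq)) for p in dataset.library.read_pairs),
    )
    write_fastq(
        outdir / "reads_R2.fastq.gz",
        ((p.id, p.read2_seq, p.read2_qual or "?" * len(p.read2_seq)) for p in dataset.library.read_pairs),
    )
    pd.DataFrame(
        [
            {"read_id": p.id, "line_id": p.library.line_id, "border": p.library.border,
             "walking_primer_id": p.library.walking_primer_id}
            for p in dataset.library.read_pairs
        ]
    ).to_csv(outdir / "library_sheet.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "construct_id": t.construct_id, "chromosome": t.chromosome,
                "position": t.position, "ref_position": t.ref_position,
                "orientation": t.orientation,
                "lb_truncation": t.lb_truncation, "rb_truncation": t.rb_truncation,
                "insert_length": t.insert_length,
                "amplicons_LB": t.amplicons_per_border["LB"],
                "amplicons_RB": t.amplicons_per_border["RB"],
            }
            for t in dataset.truths
        ]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
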