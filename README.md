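# tdnawalk

Detection of T-DNA insertion sites in plant genomes from genome-walking
amplicon sequencing, with downstream PCR-based zygosity genotyping and
walking-primer motif selection — plus a ground-truthed simulator that makes
the whole pipeline testable without any external dataset.

## Who this is for

*Agrobacterium*-mediated transformation integrates the T-DNA cassette at
essentially random genomic positions and copy numbers. Anyone building
stable transgenic lines — especially stacked, multi-construct lines in a
polyploid crop such as allohexaploid *Camelina sativa* — needs to know
**where** each insertion landed and, in the next generation, **which plants
are homozygous** at each locus. This package implements the computational
half of a bench-friendly workflow: a two-phase walking PCR amplifies from a
border-specific primer across the T-DNA/plant junction to a semi-random
walking primer anchored on a palindromic hexamer motif; paired 150 bp reads
(read 2 at the transgene end, read 1 at the walking end) are then resolved
to ranked, orientation-annotated insertion sites.

## What it computes

1. **Vector trimming** (`tdnawalk.vector_trim`). Each read 2 is locally
   aligned to the T-DNA vector(s) with scores (+2, −3; gap 5 + 2k) and kept
   only if the best placement beats the runner-up by a margin (the MAPQ > 10
   analog). The unaligned *border-distal* read terminus — the plant genomic
   arm, computed from the alignment's position and strand relative to the
   border (the 5′-clip-for-LB / 3′-clip-for-RB rule as a special case) — is
   emitted as a fragment if ≥ 20 bp; an unmapped read 1 is emitted whole.
   Fragments are deduplicated by exact sequence.
2. **Genome search** (`tdnawalk.genome_search`). A seed-and-extend
   nucleotide search (word size 11, two-hit seeding, gapped extension) with
   Karlin–Altschul statistics, E = K·m′·n′·e^(−λS), filtered at ≥ 95%
   identity and E ≤ 10⁻¹⁰. All passing placements are reported: in a
   hexaploid a fragment legitimately hits its locus on all three homeologous
   subgenomes ("hits in triplets").
3. **Site calling** (`tdnawalk.site_caller`). Hits are chained into hotspots
   (1 kb single-linkage), grouped across homeologs by shared supporting
   fragments, and ranked hierarchically: both-border support within 1 kb
   first, then the number of satisfied weighting criteria (multiple PCR
   libraries; E < 10⁻³⁰ or identity > 99%; a supporting read ≥ 60 bp;
   cross-line uniqueness), then raw read support. Orientation (RB-LB vs
   LB-RB) is voted from each hit's subject strand combined with its read of
   origin; homeolog groups are resolved when one member leads by > 0.5
   identity points **and** ≥ 2× top-placement support, else kept as a tie.
   Verification-primer windows 250–500 bp either side of the junction are
   emitted for external primer design.
4. **Zygosity** (`tdnawalk.zygosity`). The two-PCR calculus per plant ×
   locus: anchored PCR **A** (genomic + transgene primer) and flanking PCR
   **B** (genomic primers across the locus) give +/+ → heterozygous, +/− →
   homozygous, −/+ → wildtype null, −/− → assay failure; per-locus summaries
   include a χ² test against the 2:1:1 expectation for selfed hemizygotes
   and the (1/4)^k gene-stacking homozygosity probability.
5. **Motif tools** (`tdnawalk.motifs`). Genome-wide scanning of candidate
   palindromic hexamers, in-silico amplicon counting (30 bp – 2 kb), and
   ranking by moderate frequency + cross-chromosome uniformity.
6. **Simulator** (`tdnawalk.simulator`). Polyploid genomes (n subgenomes at
   a configurable divergence), cassette insertion with orientation and
   border truncation, the full two-phase amplicon geometry with size
   selection (150–1200 bp), sequencing error, PCR duplicates, background
   mispriming, and Mendelian / homozygous-lethal T₂ segregation — all
   bit-reproducible from a seed, with truth tables for every read.

## Worked example

`python examples/03_zygosity_screen.py` genotypes the bundled 19-plant,
three-locus T₂ screen of a hexaploid camelina line and prints:

```
chr15_982591: het=8 hmz=6 null=5  (carriers: 57.14% het / 42.86% hmz)  chi2=0.58 p=0.749
chr18_7461224: het=12 hmz=7 null=0  (carriers: 63.16% het / 36.84% hmz)  chi2=6.47 p=0.039  ** non-Mendelian
chr8_24442089: het=19 hmz=0 null=0  (carriers: 100.0% het / 0.0% hmz)  chi2=19.00 p=0.000  ** non-Mendelian
```

The first locus segregates cleanly (8 heterozygous : 6 homozygous : 5 null
segregants; 57.14% of carriers heterozygous). The second lacks null
segregants among the antibiotic-selected plants, and the third shows *no*
homozygotes at all — the flagged signature of a homozygous-lethal or
rearranged insertion that PCR genotyping alone would misread as "all
heterozygous".

`python examples/02_simulate_and_detect.py` simulates a 2-insertion
library on a 3-subgenome genome and recovers both insertions:

```
  site_1  chr1B:11874-13699  both_borders=True  orientation=RB-LB  homeologs=resolved(chr1B)  transgene=construct1
  site_2  chr2C:37554-37724  both_borders=False  orientation=LB-RB  homeologs=resolved(chr2C)  transgene=construct2
```

Both calls match the planted truth (chr1B:12732 RB-LB; chr2C:37553 LB-RB),
including the correct homeolog out of the three near-identical subgenome
copies and the absent right-border support for the second insertion (its RB
flank has no walking motif in amplifiable range).

A thin CLI mirrors the library: `tdnawalk simulate | motifs | trim |
search | call-sites | zygosity | detect` (see `tdnawalk --help`).

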