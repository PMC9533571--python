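# Methods

This note documents the models, parameter choices and numerical decisions
behind tdnawalk, and what the simulator does and does not emulate.

## The amplicon model

The package assumes the two-phase genome-walking library design: a
high-temperature linear phase in which only a transgene-specific border
primer extends (enriching junction-containing template ~(1 + c)-fold after
c cycles — 19× for the standard 18), followed by a low-temperature
exponential phase in which walking primers anneal at fixed 6-bp palindromic
motifs. Every informative amplicon therefore runs from a nested border
primer inside the T-DNA, across the border/plant junction, to a walking
motif occurrence in the flanking genome, and is sequenced as a 2×150 bp
pair with the transgene end read as read 2 (it is adjacent to the P7
adapter) and the walking end as read 1. Everything downstream — clip
sidedness, orientation inference, hotspot geometry — is derived from this
single geometric picture.

## Vector trimming and the confidence filter

Reads are locally aligned to the vector with match +2, mismatch −3 and gap
cost 5 + 2k (the common nucleotide-search scheme; a length-k gap costs open
5 plus k extensions of 2). Because mapping quality is aligner-specific, the
"confidently mapped" condition is expressed directly: best local score
≥ 40 (i.e. a ≥ 20 bp perfect match) and best-minus-second-best margin ≥ 10,
where the runner-up is the best placement on any other vector, the other
strand, or the same vector with the winning interval excised. A read
matching a repeat present twice in the vector scores margin 0 and is
rejected, which is exactly what a MAPQ floor would do.

For throughput, the aligner first locates the candidate vector region with
a bit-parallel infix edit-distance scan (edlib) and then scores only that
region (±40 bp) exactly with Biopython's local `PairwiseAligner`. The
windowed path equals the exact search whenever the edit-distance optimum
and score optimum coincide — true for reads with a single credible vector
placement; ambiguous placements are the margin filter's job, which probes
the alternatives explicitly. The exact full-reference aligner
(`local_align`) remains the public operation and is the one validated
against an independent quadratic dynamic-programming oracle in the tests.

Clip sidedness is computed, not hard-coded: the emitted fragment is the
read terminus that, given the alignment's position and strand on the
vector, points past the targeted border into the plant genome. For a
vector recorded LB→RB this reduces to the familiar "5′ clips for LB
libraries, 3′ clips for RB libraries" on forward-aligned reads, but remains
correct for reverse-recorded vectors and reverse-aligned reads. Fragments
shorter than 20 bp are discarded; deduplication is exact string identity,
first occurrence kept, with no re-orientation (fragments keep read
orientation, matching a read-level unique filter).

Adapter trimming removes the longest 3′-terminal suffix that begins with
the adapter (≥ 8 bp overlap, ≤ 10% mismatches); bases beyond the matched
adapter are treated as read-through noise. With the simulator's size
selection at ≥ 150 bp inserts and 150 bp reads, read-through arises only
when the selection window is lowered — the geometry places read-through at
insert < read length, not below 2× read length.

## Genome search statistics

The search is seed-and-extend: an exact 11-mer index over the forward
genome strand (both query orientations scanned), two-hit seeding (a
candidate region must contain two word matches unless the fragment offers
fewer than four words), and gapped extension of the padded seed region with
the same scoring as above. E-values follow the Karlin–Altschul form
E = K·m′·n′·e^(−λS): λ solves Σ pᵢpⱼ·e^(λsᵢⱼ) = 1 for uniform base
composition (λ ≈ 0.637 for +2/−3) and is computed at import time; the
relative entropy H follows from the tilted distribution; K = 0.41, the
published constant for this scheme, is a configurable default. Effective
lengths use the standard correction l = ln(K·m·n)/H floored at 1.

Hits are filtered at ≥ 95% identity and E ≤ 10⁻¹⁰. The e-value ceiling is
calibrated for genome-scale databases: on the small simulated genomes used
in tests, a perfect 28 bp match scores E ≈ 10⁻⁸ and is — correctly —
rejected at 10⁻¹⁰; tests that probe short-fragment recovery therefore
scale the ceiling to the database (documented per test). No best-hit cap
is applied: homeolog triplets are informative downstream.

## Site calling

Hotspots are single-linkage chains of hit start positions with gap ≤ 1 kb,
per chromosome, strands and borders pooled. The 1 kb radius is the stated
left/right-border pairing distance; the same value is used for
within-border chaining since junction-derived hits from one insertion span
at most the size-selection window (~1.2 kb). Clustering is idempotent.

Candidate sites are homeolog groups: hotspots (across chromosomes) sharing
≥ 50% of the smaller member's supporting fragment IDs, joined by connected
components. Ranking is deterministic lexicographic — both-border support
first, then the count of satisfied weighting flags (multi-library;
E < 10⁻³⁰ or identity > 99%; longest supporting read ≥ 60 bp; cross-line
uniqueness), then total read support, then best e-value, then coordinates.
A "weighted" scheme with explicit weights was considered and rejected: the
evidence classes are ordinal, not commensurable, and a lexicographic order
makes every rank auditable. The pooled library counts as an independent
library by default (`pooled_counts_as_library`), since it is indexed
separately.

**Homeolog resolution.** A group resolves to one chromosome only if that
member leads every other by > 0.5 percentage points of mean hit identity
*and* holds ≥ 2× the runner-up's *top-placement support* — the number of
fragments whose strictly best e-value within the group lies on that member.
Top-placement support (rather than raw hit count) is what actually
separates homeologs: with substitution-only divergence nearly every
fragment hits all three copies above the filters, so raw counts are near
equal, but any fragment covering at least one diverged site places strictly
best on the true copy. At 0% divergence no fragment places strictly best
anywhere and the group is reported as a tie of all members — the correct,
conservative answer.

**Orientation.** Each hit votes from (border, read-of-pair, subject
strand): read 2 runs from the transgene outward, read 1 from the walking
primer inward, so e.g. a left-border read 2 on the + strand implies the
LB-adjacent flank extends rightward, i.e. the cassette reads RB→LB along
the + strand. A call requires ≥ 80% of informative hits to agree (the
evidence is near-unanimous in practice; the quorum guards against
chimeric/background hits), otherwise "undetermined". Orientation votes are
sufficient on their own; the relative position of LB vs RB hits is used
only to locate the junction, not to orient the insertion.

**Primer windows.** The junction is estimated as the midpoint between the
facing edges of the LB and RB support intervals (single-border sites use
the interval edge on the T-DNA side, chosen by the walking-direction
votes). Windows span 250–500 bp on each side, clipped at chromosome ends
with warnings, one window set per homeolog tie member.

## Zygosity

The A/B calculus is exhaustive over its four input combinations; (−,−) is
an assay failure and excluded from ratios. Summaries report percentages on
two denominators because published screens conventionally express all
three categories relative to *carriers* (transgene-positive plants) — the
bundled example table follows that convention — while the all-typed-plants
denominator is the statistically natural one. The χ² test defaults to
het:hmz:null = 2:1:1, the expectation among transgene-selected selfed
progeny of a hemizygote; a locus with p < 0.05 is flagged non-Mendelian,
which on real data is the signature of homozygous lethality, rearrangement
or flanking-PCR mispriming. The stacking helper returns (1/4)^k × 100
exactly: 25% for one locus, 6.25% for two, 1.5625% for three.

## The simulator

The simulator is the package's study design: 3 subgenomes × 3 chromosomes
× 0.5 Mb at 2% per-copy divergence from a shared ancestor (pairwise
homeolog identity ≈ 96%, enough to produce hit triplets while allowing
resolution), 2 cassettes of 4 kb with canonical 25 bp border repeats, 5
insertions by default, nested border primers 100 bp inside each border,
the four standard walking motifs, size selection 150–1200 bp, amplicon
depth 100×, substitution error 0.3% (≈ Q25–Q30 amplicon sequencing),
duplicate rate 10% and background mispriming 5% (amplicon libraries are
duplicate-rich; the background level matches a clean transgenic library,
not a wildtype control, which can be emulated with `dimer_rate`). Read 1
carries 10 primer-derived random bases before the motif, as the degenerate
primer region replaces genomic sequence. Divergence is substitution-only,
which keeps homeolog coordinates aligned and makes the homeolog map exact.

What it does **not** emulate, and hence what passing tests cannot show:
indels and structural errors in reads, chimeric T-DNA concatemers or
vector-backbone read-through, per-primer efficiency skew (a multiplier
exists but real libraries show >50% of yield from one primer),
quality-score structure, paralogy (only homeology), and real genomes'
repeat content — the random background makes the genome search easier than
a 780 Mb crop genome, which is why the e-value ceiling behaves differently
at desk scale (above). Truth records carry both post-insertion and
reference coordinates; detection is evaluated against the latter, since
the pipeline reports positions on the un-inserted reference.

Undetectable insertions are a modelled outcome, not a failure: an
insertion whose borders are truncated past the nested primer site, or with
no walking motif within the size window, yields zero amplicons and a
logged warning — the situation in which a real screen simply misses a
copy. Simulation fixtures used in tests state when their seed was chosen
to make the planted insertion amplifiable, so the property under test is
non-vacuous.

## Problem sizes and determinism

Test and acceptance runs use the study conditions above (4.5 Mb genome,
~1300–4000 read pairs; the orientation batch plants 50 insertions at 30×
depth). All stochastic steps draw from a single seeded generator;
identical configuration and seed reproduce outputs byte-for-byte, and the
detection pipeline itself is deterministic (every tie in ranking,
clustering and alignment selection has a stated break).

## Known limitations

Single best vector alignment per read (chimeric/split alignments are not
reassembled); no detection of vector-backbone integration or chromosomal
rearrangements; orientation requires junction-spanning or mate evidence
from at least one informative hit; homeolog resolution assumes divergence
is visible within fragment length — short fragments on recently duplicated
regions will tie; the "moderate frequency" band for motif ranking
(0.5–1.5× the candidate-set median density) is a package default, as the
underlying selection procedure's numeric thresholds are not published.
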