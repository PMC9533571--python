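"""Hotspot clustering, candidate ranking, homeolog resolution, orientation
inference and primer-window extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tdnawalk.genome_search import GenomeHit
from tdnawalk.site_caller import (
    CandidateSite,
    HomeologEvidence,
    cluster_hits,
    estimate_insertion_point,
    flag_and_rank,
    infer_orientation,
    primer_windows,
    resolve_homeologs,
)

from _oracles import brute_force_single_linkage
from conftest import random_dna


def mk_hit(
    chrom="c1",
    s_lo=1000,
    length=60,
    strand="+",
    border="LB",
    which_read=1,
    primer="PST1",
    fragment_id=None,
    evalue=1e-40,
    pident=99.5,
    line="lineA",
):
    sstart, send = (s_lo, s_lo + length - 1) if strand == "+" else (s_lo + length - 1, s_lo)
    return GenomeHit(
        fragment_id=fragment_id or f"frag_{chrom}_{s_lo}_{border}_{which_read}",
        chromosome=chrom,
        pident=pident,
        length=length,
        mismatch=0,
        gapopen=0,
        qstart=1,
        qend=length,
        sstart=sstart,
        send=send,
        evalue=evalue,
        bitscore=100.0,
        strand=strand,
        qlen=length,
        read_id=f"r_{s_lo}",
        which_read=which_read,
        border=border,
        walking_primer_id=primer,
        line_id=line,
    )


class TestClusterHits:
    def test_gap_chaining_example(self):
        hits = [mk_hit(s_lo=p) for p in (100, 600, 1900)]
        hotspots = cluster_hits(hits, gap=1000)
        assert [(hs.start, len(hs.hits)) for hs in hotspots] == [(100, 2), (1900, 1)]

    def test_empty_input(self):
        assert cluster_hits([]) == []

    def test_strands_and_borders_pooled(self):
        hits = [
            mk_hit(s_lo=100, strand="+", border="LB"),
            mk_hit(s_lo=300, strand="-", border="RB"),
        ]
        hotspots = cluster_hits(hits)
        assert len(hotspots) == 1
        assert hotspots[0].border_counts == {"LB": 1, "RB": 1}

    def test_idempotent(self, rng):
        hits = [mk_hit(s_lo=int(p)) for p in rng.integers(0, 50_000, size=60)]
        once = cluster_hits(hits)
        again = cluster_hits([h for hs in once for h in hs.hits])
        assert [(h.chromosome, h.start, h.end) for h in once] == [
            (h.chromosome, h.start, h.end) for h in again
        ]

    @given(st.lists(st.integers(0, 20_000), min_size=0, max_size=40))
    def test_matches_single_linkage_oracle(self, positions):
        hits = [mk_hit(s_lo=p, length=1) for p in positions]
        hotspots = cluster_hits(hits, gap=1000)
        oracle = brute_force_single_linkage(positions, gap=1000)
        assert [hs.n_reads for hs in hotspots] == [len(c) for c in oracle]
        assert [hs.start for hs in hotspots] == [c[0] for c in oracle]


class TestFlagAndRank:
    def test_both_border_pairing_within_1kb(self):
        hits = [mk_hit(s_lo=10_000, border="LB", fragment_id="fa"),
                mk_hit(s_lo=10_800, border="RB", fragment_id="fa")]
        sites = flag_and_rank(cluster_hits(hits))
        assert len(sites) == 1
        assert sites[0].flags["both_borders"]

    def test_both_borders_symmetric_and_order_invariant(self):
        a = [mk_hit(s_lo=10_000, border="LB", fragment_id="f1"),
             mk_hit(s_lo=10_800, border="RB", fragment_id="f1")]
        b = list(reversed(a))
        swapped = [mk_hit(s_lo=10_000, border="RB", fragment_id="f1"),
                   mk_hit(s_lo=10_800, border="LB", fragment_id="f1")]
        for hits in (a, b, swapped):
            assert flag_and_rank(cluster_hits(hits))[0].flags["both_borders"]

    def test_both_borders_beats_read_support(self):
        site_a = [mk_hit(s_lo=10_000, border="LB", fragment_id=f"a{i}") for i in range(25)] + [
            mk_hit(s_lo=10_500, border="RB", fragment_id=f"a{i}") for i in range(25, 50)
        ]
        site_b = [
            mk_hit(chrom="c2", s_lo=50_000 + (i % 3), border="LB", fragment_id=f"b{i}")
            for i in range(5000)
        ]
        sites = flag_and_rank(cluster_hits(site_a + site_b))
        assert sites[0].primary.chromosome == "c1"
        assert sites[0].rank == 1 and not sites[1].flags["both_borders"]

    def test_shared_position_across_lines_not_unique(self):
        line_a = cluster_hits([mk_hit(s_lo=10_000, fragment_id="x")])
        line_b = cluster_hits([mk_hit(s_lo=10_200, fragment_id="y", line="lineB")])
        sites_a = flag_and_rank(line_a, other_lines=[line_b])
        sites_b = flag_and_rank(line_b, other_lines=[line_a])
        assert not sites_a[0].flags["line_unique"]
        assert not sites_b[0].flags["line_unique"]

    def test_rank_matches_lexicographic_sort_oracle(self, rng):
        """20 synthetic hotspots with randomized flag combinations rank
        exactly as an independent lexicographic sort."""
        all_hits = []
        for i in range(20):
            chrom = f"c{i}"  # one hotspot per chromosome, disjoint fragments
            base = 10_000
            n_reads = int(rng.integers(1, 40))
            both = bool(rng.random() < 0.5)
            multi = bool(rng.random() < 0.5)
            strong = bool(rng.random() < 0.5)
            long_read = bool(rng.random() < 0.5)
            for j in range(n_reads):
                all_hits.append(
                    mk_hit(
                        chrom=chrom,
                        s_lo=base + int(rng.integers(0, 400)),
                        border="RB" if (both and j % 2) else "LB",
                        primer="PST2" if (multi and j % 2) else "PST1",
                        evalue=1e-40 if strong else 1e-20,
                        pident=98.0,
                        length=80 if long_read else 40,
                        fragment_id=f"{chrom}_f{j}",
                    )
                )
            if both and n_reads == 1:  # guarantee an RB mate
                all_hits.append(
                    mk_hit(chrom=chrom, s_lo=base + 500, border="RB",
                           evalue=1e-40 if strong else 1e-20, pident=98.0,
                           length=80 if long_read else 40, fragment_id=f"{chrom}_fR")
                )
        sites = flag_and_rank(cluster_hits(all_hits))
        key = lambda s: (
            not s.flags["both_borders"],
            -sum(s.flags.values()),
            -s.n_reads,
            s.best_evalue,
            s.primary.chromosome,
            s.primary.start,
        )
        assert [s.site_id for s in sites] == [
            s.site_id for s in sorted(sites, key=key)
        ]
        assert [s.rank for s in sites] == list(range(1, len(sites) + 1))


class TestResolveHomeologs:
    def test_clear_leader_resolved(self):
        status = resolve_homeologs(
            [
                HomeologEvidence("chr5", 99.8, 5000),
                HomeologEvidence("chr16", 97.0, 300),
                HomeologEvidence("chr7", 96.8, 200),
            ]
        )
        assert status.resolved and status.chromosomes == ["chr5"]

    def test_indistinguishable_members_tie(self):
        status = resolve_homeologs(
            [
                HomeologEvidence("chr5", 99.1, 900),
                HomeologEvidence("chr16", 99.05, 1000),
                HomeologEvidence("chr7", 99.0, 950),
            ]
        )
        assert not status.resolved
        assert status.chromosomes == ["chr16", "chr5", "chr7"]

    def test_identity_lead_without_support_lead_is_tie(self):
        status = resolve_homeologs(
            [HomeologEvidence("chr5", 99.8, 100), HomeologEvidence("chr16", 97.0, 90)]
        )
        assert not status.resolved

    def test_singleton_resolved(self):
        status = resolve_homeologs([HomeologEvidence("chr2", 96.0, 3)])
        assert status.resolved and status.chromosomes == ["chr2"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_homeologs([])


class TestInferOrientation:
    def _site3_pattern(self):
        """The RB-LB configuration: RB-library read 1 on +, read 2 on -,
        LB-library read 1 on -, read 2 on +."""
        return [
            mk_hit(border="RB", which_read=1, strand="+", s_lo=9_000),
            mk_hit(border="RB", which_read=2, strand="-", s_lo=9_900),
            mk_hit(border="LB", which_read=1, strand="-", s_lo=11_000),
            mk_hit(border="LB", which_read=2, strand="+", s_lo=10_100),
        ]

    def test_rb_lb_pattern(self):
        assert infer_orientation(self._site3_pattern()) == "RB-LB"

    def test_mirror_pattern_is_lb_rb(self):
        mirrored = [
            mk_hit(border=h.border, which_read=h.which_read,
                   strand="+" if h.strand == "-" else "-", s_lo=h.s_lo)
            for h in self._site3_pattern()
        ]
        assert infer_orientation(mirrored) == "LB-RB"

    def test_conflicting_evidence_undetermined(self):
        hits = [
            mk_hit(border="LB", which_read=2, strand="+"),
            mk_hit(border="LB", which_read=2, strand="-"),
        ]
        assert infer_orientation(hits) == "undetermined"

    def test_no_informative_hits_undetermined(self):
        h = mk_hit()
        h.which_read = 0
        assert infer_orientation([h]) == "undetermined"


class TestPrimerWindows:
    def _site_at(self, chrom, point, genome):
        hits = [
            mk_hit(chrom=chrom, s_lo=point - 200, length=200, border="LB", fragment_id="f1"),
            mk_hit(chrom=chrom, s_lo=point + 1, length=200, border="RB", fragment_id="f1"),
        ]
        sites = flag_and_rank(cluster_hits(hits))
        return sites[0]

    def test_window_arithmetic(self, rng):
        genome = {"c1": random_dna(rng, 1_000_000)}
        site = self._site_at("c1", 10_000, genome)
        pw = primer_windows(site, genome, flank=(250, 500))[0]
        assert pw.insertion_point == 10_000
        assert pw.upstream == (9_500, 9_750)
        assert pw.downstream == (10_250, 10_500)
        assert pw.upstream_seq == genome["c1"][9_499:9_750]

    def test_edge_clipping_one_sided(self, rng):
        genome = {"c1": random_dna(rng, 5_000)}
        hits = [mk_hit(chrom="c1", s_lo=101, length=60, border="LB", fragment_id="f1"),
                mk_hit(chrom="c1", s_lo=100, length=60, border="RB", fragment_id="f1")]
        site = flag_and_rank(cluster_hits(hits))[0]
        pw = primer_windows(site, genome, flank=(250, 500))[0]
        assert pw.upstream is None
        assert pw.warnings

    def test_windows_free_of_transgene(self, small_dataset, small_detection):
        """Cross-module: primer windows extracted from the reference never
        contain inserted construct sequence."""
        construct_words = {
            seq[i : i + 30]
            for seq in small_dataset.constructs.values()
            for i in range(0, len(seq) - 30, 10)
        }
        checked = 0
        for site in small_detection.sites:
            for pw in primer_windows(site, small_dataset.genome):
                for seq in (pw.upstream_seq, pw.downstream_seq):
                    if seq is None:
                        continue
                    checked += 1
                    assert not any(w in seq for w in construct_words)
        assert checked > 0


def test_insertion_point_estimate_between_borders():
    hits = [
        mk_hit(s_lo=9_000, length=500, border="LB", fragment_id="f1"),
        mk_hit(s_lo=10_020, length=500, border="RB", fragment_id="f1"),
    ]
    hotspot = cluster_hits(hits)[0]
    point = estimate_insertion_point(hotspot)
    assert 9_499 <= point <= 10_021
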