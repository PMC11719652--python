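"""Homology-map loading, interval lifting and target band labeling."""

import io

import numpy as np
import pytest

from karyocna import rat1
from karyocna.bands import CNARegion, CytobandMap, GenomicInterval
from karyocna.simdata import simulate_cytoband_map, simulate_homology_map
from karyocna.xmap import (
    HomologyMap,
    HomologyValidationError,
    SyntenyBlock,
    intervals_to_band_span,
    lift_interval,
    load_homology_map,
    translate_cna_profile,
    write_homology_map,
)


def identity_map(cmap: CytobandMap) -> HomologyMap:
    return HomologyMap(tuple(
        SyntenyBlock(GenomicInterval(c, 0, cmap.chrom_length(c)),
                     GenomicInterval(c, 0, cmap.chrom_length(c)), "+")
        for c in cmap.chromosomes
    ))


class TestLoad:
    def test_block_tsv_round_trip(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=3)
        fwd, _ = simulate_homology_map(small_cfg, cmap, seed=4)
        buf = io.StringIO()
        write_homology_map(fwd, buf)
        buf.seek(0)
        reloaded = load_homology_map(buf)
        assert reloaded.blocks == fwd.blocks

    def test_overlapping_source_blocks_rejected(self):
        blocks = (
            SyntenyBlock(GenomicInterval("1", 0, 100),
                         GenomicInterval("t1", 0, 100), "+"),
            SyntenyBlock(GenomicInterval("1", 50, 150),
                         GenomicInterval("t1", 100, 200), "+"),
        )
        with pytest.raises(HomologyValidationError, match="overlap"):
            HomologyMap(blocks)

    def test_minimal_chain_file(self):
        # one chain, two ungapped runs: sizes 100 and 50, with a 10/20
        # double-sided gap between them
        chain = (
            "chain 1000 chr1 1000 + 100 280 chrA 2000 + 500 680 1\n"
            "100 10 20\n"
            "50\n"
        )
        hmap = load_homology_map(io.StringIO(chain), dialect="ucsc_chain")
        assert len(hmap.blocks) == 2
        b1, b2 = hmap.blocks
        assert (b1.source.start, b1.source.end) == (100, 200)
        assert (b1.target.start, b1.target.end) == (500, 600)
        assert (b2.source.start, b2.source.end) == (210, 260)
        assert (b2.target.start, b2.target.end) == (620, 670)

    def test_chain_negative_query_strand_flips_coordinates(self):
        chain = (
            "chain 1000 chr1 1000 + 0 100 chrA 500 - 0 100 1\n"
            "100\n"
        )
        hmap = load_homology_map(io.StringIO(chain), dialect="ucsc_chain")
        (b,) = hmap.blocks
        assert b.strand == "-"
        assert (b.target.start, b.target.end) == (400, 500)


def lift_point(hmap: HomologyMap, chrom: str, pos: int):
    """Independent per-point oracle."""
    for b in hmap.blocks:
        if (b.source.chromosome == chrom
                and b.source.start <= pos < b.source.end):
            offset = pos - b.source.start
            s_len = b.source.end - b.source.start
            if b.strand == "+":
                return (b.target.chromosome, b.target.start + offset)
            return (b.target.chromosome, b.target.end - 1 - offset)
    return None


class TestLift:
    def test_identity_map_is_identity(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=6)
        hmap = identity_map(cmap)
        q = GenomicInterval("1", 10, cmap.chrom_length("1") - 5)
        assert lift_interval(hmap, q, min_fragment=0, gap_join=0) == [q]

    def test_two_block_inversion_against_point_oracle(self):
        hmap = HomologyMap((
            SyntenyBlock(GenomicInterval("1", 0, 100),
                         GenomicInterval("t1", 0, 100), "+"),
            SyntenyBlock(GenomicInterval("1", 100, 200),
                         GenomicInterval("t2", 300, 400), "-"),
        ))
        q = GenomicInterval("1", 50, 150)
        frags = lift_interval(hmap, q, min_fragment=0, gap_join=0)
        assert len(frags) == 2
        images = {lift_point(hmap, "1", p) for p in range(q.start, q.end)}
        covered = {
            (f.chromosome, p) for f in frags for p in range(f.start, f.end)}
        assert images == covered

    def test_no_overlap_returns_empty(self):
        hmap = HomologyMap((SyntenyBlock(GenomicInterval("1", 0, 100),
                                         GenomicInterval("t1", 0, 100), "+"),))
        assert lift_interval(hmap, GenomicInterval("2", 0, 50)) == []

    def test_lift_matches_point_oracle_on_simulated_maps(self, small_cfg):
        rng = np.random.default_rng(0)
        cmap = simulate_cytoband_map(small_cfg, seed=8)
        fwd, _ = simulate_homology_map(small_cfg, cmap, seed=9)
        for _ in range(50):
            chrom = cmap.chromosomes[int(rng.integers(len(cmap.chromosomes)))]
            L = cmap.chrom_length(chrom)
            a = int(rng.integers(0, L - 1))
            b = int(rng.integers(a + 1, L + 1))
            q = GenomicInterval(chrom, a, b)
            frags = lift_interval(fwd, q, min_fragment=0, gap_join=0)
            # strand-inverted blocks preserve fragment lengths: total
            # lifted length equals query length on a fully tiling map
            assert sum(len(f) for f in frags) == len(q)
            for p in sorted(rng.integers(a, b, size=25).tolist()):
                tgt = lift_point(fwd, chrom, int(p))
                assert any(f.chromosome == tgt[0]
                           and f.start <= tgt[1] < f.end for f in frags)

    def test_round_trip_through_inverse(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=12)
        fwd, inv = simulate_homology_map(small_cfg, cmap, seed=13)
        rng = np.random.default_rng(1)
        for _ in range(25):
            chrom = cmap.chromosomes[int(rng.integers(len(cmap.chromosomes)))]
            L = cmap.chrom_length(chrom)
            a = int(rng.integers(0, L - 1))
            b = int(rng.integers(a + 1, L + 1))
            frags = lift_interval(fwd, GenomicInterval(chrom, a, b),
                                  min_fragment=0, gap_join=0)
            back = [
                piece
                for f in frags
                for piece in lift_interval(inv, f, min_fragment=0, gap_join=0)
            ]
            same = sorted((p.start, p.end) for p in back
                          if p.chromosome == chrom)
            assert sum(e - s for s, e in same) == b - a
            assert same[0][0] == a and same[-1][1] == b

    def test_output_independent_of_block_order(self):
        blocks = [
            SyntenyBlock(GenomicInterval("1", 0, 100),
                         GenomicInterval("t1", 0, 100), "+"),
            SyntenyBlock(GenomicInterval("1", 100, 200),
                         GenomicInterval("t2", 0, 100), "-"),
            SyntenyBlock(GenomicInterval("1", 200, 300),
                         GenomicInterval("t1", 100, 200), "+"),
        ]
        q = GenomicInterval("1", 20, 280)
        a = lift_interval(HomologyMap(tuple(blocks)), q, 0, 0)
        b = lift_interval(HomologyMap(tuple(reversed(blocks))), q, 0, 0)
        assert a == b

    def test_short_fragments_dropped_and_gaps_joined(self):
        hmap = HomologyMap((
            SyntenyBlock(GenomicInterval("1", 0, 100),
                         GenomicInterval("t1", 0, 100), "+"),
            SyntenyBlock(GenomicInterval("1", 100, 200),
                         GenomicInterval("t1", 150, 250), "+"),
        ))
        q = GenomicInterval("1", 95, 200)
        # 5-base fragment dropped below min_fragment
        frags = lift_interval(hmap, q, min_fragment=10, gap_join=0)
        assert frags == [GenomicInterval("t1", 150, 250)]
        # kept and gap-joined across the 50-base target gap
        frags = lift_interval(hmap, q, min_fragment=0, gap_join=60)
        assert frags == [GenomicInterval("t1", 95, 250)]


class TestBandSpanLabels:
    def test_paper_style_label(self):
        hg = rat1.human_cytobands()
        labels = intervals_to_band_span(
            hg, [GenomicInterval("5", 8_000_000, 28_000_000)])
        assert labels == ["5p15.31p14.1"]

    def test_single_band_collapses(self):
        hg = rat1.human_cytobands()
        labels = intervals_to_band_span(
            hg, [GenomicInterval("5", 8_500_000, 9_000_000)])
        assert labels == ["5p15.31"]

    def test_terminal_labels(self):
        hg = rat1.human_cytobands()
        labels = intervals_to_band_span(
            hg, [GenomicInterval("17", 40_000_000, 62_988_804)])
        assert labels == ["17q21.31qter"]

    def test_beyond_chromosome_length_rejected(self):
        hg = rat1.human_cytobands()
        with pytest.raises(ValueError, match="beyond"):
            intervals_to_band_span(hg, [GenomicInterval("17", 0, 10**9)])

    def test_labels_match_linear_scan(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=20)
        rng = np.random.default_rng(2)
        for _ in range(50):
            chrom = cmap.chromosomes[int(rng.integers(len(cmap.chromosomes)))]
            L = cmap.chrom_length(chrom)
            a = int(rng.integers(0, L - 1))
            b = int(rng.integers(a + 1, L + 1))
            (label,) = intervals_to_band_span(
                cmap, [GenomicInterval(chrom, a, b)])
            overlapped = [name for name, s, e in cmap.bands[chrom]
                          if s < b and e > a]
            first = ("pter" if a == 0 and cmap.has_p_arm(chrom)
                     else overlapped[0])
            last = "qter" if b == L else overlapped[-1]
            expected = (f"{chrom}{first}" if first == last
                        else f"{chrom}{first}{last}")
            assert label == expected


class TestTranslateProfile:
    def test_empty_input(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=30)
        fwd, _ = simulate_homology_map(small_cfg, cmap, seed=31)
        assert translate_cna_profile([], fwd, cmap) == []

    def test_identity_composition_preserves_labels(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=33)
        hmap = identity_map(cmap)
        chrom = cmap.chromosomes[0]
        L = cmap.chrom_length(chrom)
        region = CNARegion(GenomicInterval(chrom, 0, L), delta=+1,
                           label="whole")
        (out,) = translate_cna_profile([region], hmap, cmap,
                                       min_fragment=0, gap_join=0)
        assert out.interval == region.interval
        assert out.delta == +1
        (expected,) = intervals_to_band_span(cmap, [region.interval])
        assert out.label == expected

    def test_coarse_fixture_reproduces_representative_labels(self):
        translated = translate_cna_profile(
            rat1.cna_regions(), rat1.coarse_homology_map(),
            rat1.human_cytobands())
        got = {(t.label, t.delta) for t in translated}
        assert ("5p15.31p14.1", 4) in got
        assert ("16q12.2q22.1", 2) in got
        assert ("17q21.31qter", 1) in got
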