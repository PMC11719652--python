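"""Coordinate resolution, copy-number bookkeeping and CNA reduction."""

import io

import pytest

from karyocna.bands import (
    BandLookupError,
    CytobandMap,
    CytobandValidationError,
    InconsistentKaryotypeError,
    derive_copy_number_profile,
    load_cytoband_table,
    locus_to_coordinate,
    profile_to_cna_regions,
    read_bed,
    segment_to_interval,
    write_bed,
    write_cna_table,
    write_cytoband_table,
)
from karyocna.iscn import (
    BandLocus,
    UncertaintyPolicy,
    parse_karyotype,
    parse_segment,
)
from karyocna.simdata import simulate_cytoband_map, simulate_karyotype


class TestCytobandMap:
    def test_fixture_chr19_length(self, rat1_map):
        assert rat1_map.chrom_length("19") == 72_914_587

    def test_single_band_map_valid(self):
        cmap = CytobandMap(bands={"1": (("q11", 0, 100),)})
        assert cmap.chrom_length("1") == 100

    def test_gap_rejected(self):
        tsv = "chr1\t0\t50\tq11\tgneg\nchr1\t60\t100\tq12\tgneg\n"
        with pytest.raises(CytobandValidationError, match="gap.*q11.*q12"):
            load_cytoband_table(io.StringIO(tsv))

    def test_overlap_rejected(self):
        tsv = "chr1\t0\t50\tq11\tgneg\nchr1\t40\t100\tq12\tgneg\n"
        with pytest.raises(CytobandValidationError, match="overlap"):
            load_cytoband_table(io.StringIO(tsv))

    def test_simulated_map_write_read_round_trip(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=5)
        buf = io.StringIO()
        write_cytoband_table(cmap, buf)
        buf.seek(0)
        reloaded = load_cytoband_table(buf)
        assert reloaded.bands == cmap.bands


class TestLocusToCoordinate:
    def test_pter_is_zero(self, rat1_map):
        locus = BandLocus("7", "p", "", terminal="pter")
        assert locus_to_coordinate(rat1_map, locus) == 0

    def test_qter_is_chromosome_length(self, rat1_map):
        locus = BandLocus("19", "q", "", terminal="qter")
        assert locus_to_coordinate(rat1_map, locus) == 72_914_587

    def test_band_sides(self, rat1_map):
        locus = BandLocus("2", "q", "34")
        assert locus_to_coordinate(rat1_map, locus, "proximal") == 192_680_325
        assert locus_to_coordinate(rat1_map, locus, "distal") == 210_000_000

    def test_unknown_band_lists_neighbors(self, rat1_map):
        with pytest.raises(BandLookupError, match="q99.*known bands"):
            locus_to_coordinate(rat1_map, BandLocus("2", "q", "99"))

    def test_synthetic_lookup_matches_table(self, small_cfg):
        cmap = simulate_cytoband_map(small_cfg, seed=9)
        for chrom, blist in cmap.bands.items():
            for name, start, end in blist:
                locus = BandLocus(chrom, name[0], name[1:])
                assert locus_to_coordinate(cmap, locus, "proximal") == start
                assert locus_to_coordinate(cmap, locus, "distal") == end


class TestSegmentToInterval:
    def test_uncertain_band_range_spans_resolution(self, rat1_map,
                                                   rat1_policy):
        seg = parse_segment("2q?2->2q?2")
        iv = segment_to_interval(rat1_map, seg, rat1_policy)
        assert (iv.start, iv.end) == (80_406_982, 139_816_749)
        assert iv.span_1based == "80406983-139816749"

    def test_whole_chromosome(self, rat1_map):
        iv = segment_to_interval(rat1_map, parse_segment("7pter->7qter"))
        assert iv.span_1based == "1-143501887"

    def test_certain_breakpoints_partition_the_chromosome(self, rat1_map):
        """Complementary segments sharing the p11 breakpoint must tile
        chr19 without overlap (reciprocal translocation bookkeeping)."""
        p_arm = segment_to_interval(rat1_map, parse_segment("19p11->19pter"))
        q_arm = segment_to_interval(rat1_map, parse_segment("19qter->19p11"))
        assert (p_arm.start, p_arm.end) == (0, 27_543_415)
        assert (q_arm.start, q_arm.end) == (27_543_415, 72_914_587)

    def test_zero_length_segment_rejected(self, rat1_map):
        with pytest.raises(ValueError, match="zero-length"):
            segment_to_interval(rat1_map, parse_segment("2q34->2q34"))


def _grid_coverage(cmap, model, rule, policy, chrom, points):
    """Brute-force coverage oracle: enumerate every chromosome copy and
    derivative segment, count how many cover each grid point."""
    from karyocna.iscn import expand_model

    model = expand_model(model, rule)
    counts = []
    baseline = (model.sex.count(chrom) if chrom in "XY"
                else model.ploidy_base)
    for p in points:
        n = baseline
        for ev in model.numericals:
            if ev.chromosome == chrom:
                n += ev.delta
        for d in model.derivatives:
            if d.prefix == "replacement" and d.named_chromosome == chrom:
                n -= 1
            for seg in d.segments:
                if seg.chromosome != chrom:
                    continue
                iv = segment_to_interval(cmap, seg, policy)
                if iv.start <= p < iv.end:
                    n += 1
        counts.append(n)
    return counts


class TestDeriveProfile:
    def test_baseline_profile(self, rat1_map):
        profile = derive_copy_number_profile(
            parse_karyotype("42<2n>,XY"), rat1_map)
        for chrom in rat1_map.chromosomes:
            expected = 1 if chrom in ("X", "Y") else 2
            assert profile.segments[chrom] == (
                (0, rat1_map.chrom_length(chrom), expected),)

    def test_rat1_key_counts(self, rat1_map, rat1_model, rat1_rule,
                             rat1_policy):
        profile = derive_copy_number_profile(rat1_model, rat1_map,
                                             rat1_rule, rat1_policy)
        # monosomy 8, trisomy 7 genome-wide
        assert profile.segments["8"] == ((0, 132_457_389, 1),)
        assert profile.segments["7"] == ((0, 143_501_887, 3),)
        # the 2q2 band group: 2 baseline + 4 derivative segments
        assert profile.count_at("2", 100_000_000) == 6
        assert profile.count_at("2", 200_000_000) == 1  # distal 2q lost
        assert profile.count_at("19", 1_000_000) == 4   # 19p: 2 + 2
        assert profile.count_at("19", 50_000_000) == 3  # 19q: 2 + 1

    def test_event_on_absent_chromosome_errors(self, rat1_map):
        with pytest.raises(InconsistentKaryotypeError):
            derive_copy_number_profile(parse_karyotype("41<2n>,XX,-Y"),
                                       rat1_map)

    def test_negative_count_rejected(self, rat1_map):
        with pytest.raises(InconsistentKaryotypeError,
                           match="negative copy count"):
            derive_copy_number_profile(
                parse_karyotype("39<2n>,XY,-5,-5,-5"), rat1_map)

    def test_conservation_and_grid_oracle(self, small_cfg):
        rule, policy = None, UncertaintyPolicy()
        for seed in range(40):
            cmap = simulate_cytoband_map(small_cfg, seed=[31, seed])
            text, _ = simulate_karyotype(small_cfg, cmap, seed=[32, seed])
            model = parse_karyotype(text)
            profile = derive_copy_number_profile(model, cmap)
            assert (profile.total_mass() - profile.baseline_mass()
                    == profile.event_mass())
            for chrom in cmap.chromosomes:
                L = cmap.chrom_length(chrom)
                points = list(range(0, L, max(1, L // 23))) + [L - 1]
                expected = _grid_coverage(cmap, model, rule, policy,
                                          chrom, points)
                got = [profile.count_at(chrom, p) for p in points]
                assert got == expected


class TestCNARegions:
    def test_rat1_table(self, rat1_regions):
        table = {r.label: r.delta for r in rat1_regions}
        assert table["2q22->2q25"] == +4
        assert table["2q34->2qter"] == -1
        assert table["4pter->4qter"] == -1   # p stub absorbed at 10 Mb
        assert table["7pter->7qter"] == +1
        assert table["8pter->8qter"] == -1
        assert table["19pter->19p11"] == +2
        assert table["6q11->6qter"] == +1
        assert table["10q32.1->10qter"] == +1
        # mechanical bookkeeping: both +der(12)s carry the 12p segment
        assert table["12pter->12q12"] == +2
        prov = {r.label: r.provenance for r in rat1_regions}
        assert len(prov["12pter->12q12"]) == 2

    def test_stub_zero_keeps_exact_bookkeeping(self, rat1_model, rat1_map,
                                               rat1_rule, rat1_policy):
        profile = derive_copy_number_profile(rat1_model, rat1_map,
                                             rat1_rule, rat1_policy)
        regions = profile_to_cna_regions(profile, rat1_map, stub_tolerance=0)
        table = {r.label: r.delta for r in regions}
        assert table["4pter->4p11"] == -2  # both chr4 copies lack the stub
        assert table["4q11->4qter"] == -1

    def test_flat_profile_yields_no_regions(self, rat1_map):
        profile = derive_copy_number_profile(parse_karyotype("42<2n>,XY"),
                                             rat1_map)
        assert profile_to_cna_regions(profile, rat1_map) == []

    def test_event_order_does_not_matter(self, rat1_map):
        a = parse_karyotype("43<2n>,XY,+7,-8,der(2)t(2;19)(q34;p11)")
        b = parse_karyotype("43<2n>,XY,der(2)t(2;19)(q34;p11),-8,+7")
        ra = profile_to_cna_regions(
            derive_copy_number_profile(a, rat1_map), rat1_map)
        rb = profile_to_cna_regions(
            derive_copy_number_profile(b, rat1_map), rat1_map)
        assert [(r.label, r.delta) for r in ra] == \
            [(r.label, r.delta) for r in rb]

    def test_noiseless_recovery_matches_generator_truth(self, small_cfg):
        for seed in range(30):
            cmap = simulate_cytoband_map(small_cfg, seed=[41, seed])
            text, truth = simulate_karyotype(small_cfg, cmap, seed=[42, seed])
            profile = derive_copy_number_profile(parse_karyotype(text), cmap)
            regions = profile_to_cna_regions(profile, cmap, stub_tolerance=0)
            got = sorted((r.interval.chromosome, r.interval.start,
                          r.interval.end, r.delta) for r in regions)
            assert got == sorted(truth.cna)


class TestReports:
    def test_printed_spans_are_one_based_inclusive(self, rat1_regions):
        buf = io.StringIO()
        write_cna_table(rat1_regions, buf)
        text = buf.getvalue()
        assert "19pter->19p11\t+2\t1-27543415" in text
        assert "2q22->2q25\t+4\t80406983-139816749" in text

    def test_empty_table_is_header_only(self):
        buf = io.StringIO()
        write_cna_table([], buf)
        lines = buf.getvalue().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("chromosome")

    def test_bed_round_trip(self, rat1_regions):
        buf = io.StringIO()
        write_bed(rat1_regions, buf)
        buf.seek(0)
        back = read_bed(buf)
        assert [(iv.chromosome, iv.start, iv.end, d) for iv, d in back] == [
            (r.interval.chromosome, r.interval.start, r.interval.end,
             r.delta) for r in rat1_regions]
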