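"""Construct model: validation, coordinate arithmetic, amplicons,
microdeletion design and genomic-variant application."""

import numpy as np
import pytest

from minisplice.construct import (GenomicVariant, apply_genomic_variant,
                                  build_construct, derive_site_class,
                                  design_microdeletions, total_insert_length,
                                  amplicon_length, variant_region)
from minisplice.errors import (CoordinateError, DesignError,
                               NoAmplificationError, StructureError)
from minisplice.hgvs import CPos, parse_c_hgvs, parse_cpos
from minisplice.simulate import SyntheticGeneSpec, make_synthetic_minigene
from minisplice.splice import SpliceEvent, apply_splice_events


class TestFixtureConstruct:
    def test_shape(self, mgbr2):
        assert len(mgbr2.exons) == 7
        assert sum(e.length for e in mgbr2.exons) == 1625
        # shortened-intron pieces merged: strict alternation remains
        roles = [s.role for s in mgbr2.segments[1:-1]]
        assert all(a != b for a, b in zip(roles, roles[1:]))

    def test_insert_length(self, mgbr2):
        assert total_insert_length(mgbr2) == 5837

    def test_wildtype_amplicons(self, mgbr2, primers):
        fl = apply_splice_events(mgbr2)
        rev = primers["RTpSAD-RV"]
        assert amplicon_length(fl, primers["RTBR2_ex16FW"], rev) == 1012
        assert amplicon_length(fl, primers["SD6-PSPL3_RTFW"], rev) == 1806

    @pytest.mark.parametrize("exon,expected", [("EX17", 841), ("EX18", 657)])
    def test_skip_amplicon_drops_by_exon_length(self, mgbr2, primers, exon,
                                                expected):
        t = apply_splice_events(mgbr2, {SpliceEvent("exon_skip", exon)})
        assert amplicon_length(t, primers["RTBR2_ex16FW"],
                               primers["RTpSAD-RV"]) == expected

    def test_skip_of_primer_exon_kills_amplification(self, mgbr2, primers):
        t = apply_splice_events(mgbr2, {SpliceEvent("exon_skip", "EX16")})
        with pytest.raises(NoAmplificationError):
            amplicon_length(t, primers["RTBR2_ex16FW"], primers["RTpSAD-RV"])

    @pytest.mark.parametrize("exon", ["EX14", "EX15", "EX16", "EX17",
                                      "EX18", "EX19", "EX20"])
    def test_any_skip_reduces_sd6_amplicon_by_exon_length(self, mgbr2,
                                                          primers, exon):
        t = apply_splice_events(mgbr2, {SpliceEvent("exon_skip", exon)})
        size = amplicon_length(t, primers["SD6-PSPL3_RTFW"],
                               primers["RTpSAD-RV"])
        assert size == 1806 - mgbr2.segment(exon).length


class TestBuildValidation:
    def test_minimal_single_exon_construct(self):
        c = build_construct({"name": "mini", "segments": [
            {"role": "vector_exon", "label": "V1", "length": 50},
            {"role": "intron", "label": "I1", "length": 30},
            {"role": "exon", "label": "EX", "length": 60,
             "c_start": 1, "c_end": 60},
            {"role": "intron", "label": "I2", "length": 30},
            {"role": "vector_exon", "label": "V2", "length": 50}]})
        assert total_insert_length(c) == 120

    def test_anchor_length_mismatch_rejected(self):
        with pytest.raises(CoordinateError):
            build_construct({"segments": [
                {"role": "vector_exon", "label": "V1", "length": 50},
                {"role": "intron", "label": "I1", "length": 30},
                {"role": "exon", "label": "EX17", "length": 170,
                 "c_start": 7806, "c_end": 7976},
                {"role": "intron", "label": "I2", "length": 30},
                {"role": "vector_exon", "label": "V2", "length": 50}]})

    def test_adjacent_exons_rejected(self):
        with pytest.raises(StructureError):
            build_construct({"segments": [
                {"role": "vector_exon", "label": "V1", "length": 50},
                {"role": "exon", "label": "A", "length": 30,
                 "c_start": 1, "c_end": 30},
                {"role": "exon", "label": "B", "length": 30,
                 "c_start": 31, "c_end": 60},
                {"role": "vector_exon", "label": "V2", "length": 50}]})

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(CoordinateError):
            build_construct({"segments": [
                {"role": "vector_exon", "label": "V1", "length": 50},
                {"role": "intron", "label": "I1", "length": 30},
                {"role": "exon", "label": "A", "length": 30,
                 "c_start": 100, "c_end": 129},
                {"role": "intron", "label": "I2", "length": 30},
                {"role": "exon", "label": "B", "length": 30,
                 "c_start": 50, "c_end": 79},
                {"role": "intron", "label": "I3", "length": 30},
                {"role": "vector_exon", "label": "V2", "length": 50}]})

    def test_insert_length_matches_bruteforce_on_random_constructs(self):
        for seed in range(10):
            sm = make_synthetic_minigene(SyntheticGeneSpec(
                n_exons=2 + seed % 3, seed=seed))
            expected = sum(s.length for s in sm.construct.segments
                           if s.role != "vector_exon")
            assert total_insert_length(sm.construct) == expected


class TestCoordinates:
    @pytest.mark.parametrize("text,seg,off", [
        ("7806", "EX17", 0),
        ("7976", "EX17", 170),
        ("7976+1", "IVS17", 0),
        ("7977-1", "IVS17", 484),
        ("7806-1", "IVS16", 414),
        ("7806-9", "IVS16", 406),
    ])
    def test_resolve(self, mgbr2, text, seg, off):
        idx, within = mgbr2.resolve(parse_cpos(text))
        assert mgbr2.segments[idx].label == seg
        assert within == off

    def test_out_of_range_positions(self, mgbr2):
        with pytest.raises(CoordinateError):
            mgbr2.resolve(parse_cpos("200"))
        with pytest.raises(CoordinateError):
            mgbr2.resolve(parse_cpos("7976+500"))

    @pytest.mark.parametrize("variant,expected", [
        ("c.7806-2A>G", "canonical_dinucleotide"),
        ("c.7806-1_7806-2dup", "canonical_dinucleotide"),
        ("c.7977-3_7978del", "canonical_dinucleotide"),
        ("c.8331+2T>C", "canonical_dinucleotide"),
        ("c.7976G>A", "splice_region"),     # last exonic base
        ("c.8331G>A", "splice_region"),
        ("c.7975A>G", "splice_region"),
        ("c.7977-7C>G", "splice_region"),   # intronic -7
        ("c.7806-9T>G", "intronic"),
        ("c.8009C>T", "exonic"),
        ("c.8072C>T", "exonic"),
    ])
    def test_site_class(self, mgbr2, variant, expected):
        gv = GenomicVariant.from_hgvs(variant)
        assert derive_site_class(mgbr2, gv) == expected

    @pytest.mark.parametrize("variant,region", [
        ("c.7806-9T>G", "ex17"), ("c.7976+1G>A", "ex17"),
        ("c.7977-7C>G", "ex18"), ("c.8331+2T>C", "ex18"),
        ("c.7875A>G", "ex17"), ("c.8042C>G", "ex18")])
    def test_variant_region(self, mgbr2, variant, region):
        assert variant_region(mgbr2, GenomicVariant.from_hgvs(variant)) == region


class TestMicrodeletions:
    def test_exon17_published_series(self, mgbr2):
        dels = design_microdeletions(mgbr2, "EX17", window=10,
                                     targets=[(7944, 7973)])
        assert [d.c_hgvs for d in dels] == [
            "c.7944_7953del", "c.7954_7963del", "c.7964_7973del"]

    def test_exon18_published_series_with_overlap(self, mgbr2):
        dels = design_microdeletions(mgbr2, "EX18", window=10,
                                     targets=[(7979, 8008), (8004, 8033)])
        assert [d.c_hgvs for d in dels] == [
            "c.7979_7988del", "c.7989_7998del", "c.7999_8008del",
            "c.8004_8013del", "c.8014_8023del", "c.8024_8033del"]

    def test_protected_ends_rejected(self, mgbr2):
        # includes the exon's first two nucleotides (c.7806, c.7807)
        with pytest.raises(DesignError):
            design_microdeletions(mgbr2, "EX18", window=30,
                                  targets=[(7806, 7835)])
        with pytest.raises(DesignError):
            design_microdeletions(mgbr2, "EX18", window=10,
                                  targets=[(8322, 8331)])

    def test_window_larger_than_interior_rejected(self):
        c = build_construct({"segments": [
            {"role": "vector_exon", "label": "V1", "length": 50},
            {"role": "intron", "label": "I1", "length": 30},
            {"role": "exon", "label": "EX", "length": 12,
             "c_start": 1, "c_end": 12},
            {"role": "intron", "label": "I2", "length": 30},
            {"role": "vector_exon", "label": "V2", "length": 50}]})
        with pytest.raises(DesignError):
            design_microdeletions(c, "EX", window=10)

    def test_tiling_never_touches_protected_ends(self, mgbr2):
        rng = np.random.default_rng(11)
        for _ in range(100):
            exon = mgbr2.exons[rng.integers(0, 7)]
            window = int(rng.integers(1, 31))
            dels = design_microdeletions(mgbr2, exon.label, window=window)
            for d in dels:
                a, b = d.span
                assert a.base >= exon.c_start + 2
                assert b.base <= exon.c_end - 3
                assert b.base - a.base + 1 == window


class TestApplyGenomicVariant:
    def test_exonic_deletion_shortens_exon(self, mgbr2):
        gv = GenomicVariant.from_hgvs("c.7979_8008del")
        edited = apply_genomic_variant(mgbr2, gv)
        assert edited.segment("EX18").length == 325
        assert total_insert_length(edited) == 5837 - 30

    def test_intronic_duplication_lengthens_intron(self, mgbr2):
        gv = GenomicVariant.from_hgvs("c.7806-1_7806-2dup")
        edited = apply_genomic_variant(mgbr2, gv)
        assert edited.segment("IVS16").length == \
            mgbr2.segment("IVS16").length + 2

    def test_substitution_keeps_lengths(self, mgbr2):
        gv = GenomicVariant.from_hgvs("c.7976G>A")
        edited = apply_genomic_variant(mgbr2, gv)
        assert [s.length for s in edited.segments] == \
            [s.length for s in mgbr2.segments]

    def test_boundary_spanning_deletion(self, mgbr2):
        # removes 3 intronic + 2 exonic nucleotides across the acceptor
        gv = GenomicVariant.from_hgvs("c.7977-3_7978del")
        edited = apply_genomic_variant(mgbr2, gv)
        assert edited.segment("IVS17").length == 485 - 3
        assert edited.segment("EX18").length == 355 - 2

    def test_outside_coverage_is_coordinate_error(self, mgbr2):
        with pytest.raises(CoordinateError):
            apply_genomic_variant(mgbr2,
                                  GenomicVariant.from_hgvs("c.100A>G"))

    def test_random_deletions_match_direct_arithmetic(self, mgbr2):
        rng = np.random.default_rng(5)
        base_total = sum(s.length for s in mgbr2.segments)
        for _ in range(50):
            exon = mgbr2.exons[rng.integers(0, 7)]
            k = int(rng.integers(1, 40))
            start = int(rng.integers(exon.c_start, exon.c_end - k + 1))
            gv = GenomicVariant.from_hgvs(f"c.{start}_{start + k - 1}del")
            edited = apply_genomic_variant(mgbr2, gv)
            assert sum(s.length for s in edited.segments) == base_total - k

    def test_sequence_editing_on_synthetic_gene(self, synthetic_gene):
        c = synthetic_gene.construct
        exon = c.exons[1]
        pos = exon.c_start + 5
        old = exon.sequence[5]
        alt = "A" if old != "A" else "C"
        gv = parse_and_build(f"c.{pos}{old}>{alt}")
        edited = apply_genomic_variant(c, gv)
        assert edited.segment(exon.label).sequence[5] == alt
        gv2 = parse_and_build(f"c.{pos}_{pos + 2}del")
        edited2 = apply_genomic_variant(c, gv2)
        assert edited2.segment(exon.label).sequence == \
            exon.sequence[:5] + exon.sequence[8:]


def parse_and_build(text):
    return GenomicVariant.from_hgvs(text)


class TestHgvsParsing:
    @pytest.mark.parametrize("text,kind,span", [
        ("c.7806-1G>A", "substitution", (CPos(7806, -1), CPos(7806, -1))),
        ("c.7979_8008del", "deletion", (CPos(7979), CPos(8008))),
        ("c.7806-1_7806-2dup", "duplication",
         (CPos(7806, -2), CPos(7806, -1))),   # reversed interval absorbed
        ("c.7805_7806insAG", "insertion", (CPos(7805), CPos(7806))),
        ("c.7977-3_7978del", "deletion", (CPos(7977, -3), CPos(7978))),
    ])
    def test_parse(self, text, kind, span):
        cv = parse_c_hgvs(text)
        assert cv.edit_kind == kind
        assert cv.span == span

    def test_garbage_rejected(self):
        with pytest.raises(CoordinateError):
            parse_c_hgvs("c.12xx>3")
        with pytest.raises(CoordinateError):
            parse_c_hgvs("g.7806del")
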