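"""Splice engine: event application, transcript sizes, HGVS r. strings,
candidate tables."""

import numpy as np
import pytest

from minisplice.errors import (CatalogError, CompositionError, SpanError,
                               UnsupportedDescriptionError)
from minisplice.fixtures import EVENT_CATALOG
from minisplice.simulate import SyntheticGeneSpec, make_synthetic_minigene
from minisplice.splice import (SpliceEvent, Transcript, apply_splice_events,
                               candidate_transcript_table, event_delta,
                               normalize_label, parse_rna_hgvs,
                               retained_intervals, rna_hgvs,
                               apply_alterations)

EXPECTED_DELTAS = {
    "FL": 0, "ex17 skipping": -171, "ivs16-ins8": +8, "ex17-del69": -69,
    "ex17-del20": -20, "ex17-del1": -1, "ex17-insAG": +2, "ex18-ins6": +6,
    "ex18 skipping": -355, "ex18-del191": -191, "ex18-del236": -236,
    "ex18-del309": -309, "ex18-del298": -298, "ex18-del164": -164,
    "ex18-del157": -157, "ex17-del151+ex18 skipping": -506,
    "ivs17-ret58+ex18 skipping": -297,
}

EXPECTED_RNA = {
    "FL": "r.(=)",
    "ex17 skipping": "r.7806_7976del",
    "ex17-del20": "r.7806_7825del",
    "ex17-del69": "r.7806_7874del",
    "ivs16-ins8": "r.7805_7806ins7806-8_7806-1",
    "ex17-insAG": "r.7805_7806insAG",
    "ex18 skipping": "r.7977_8331del",
    "ex18-del191": "r.7977_8167del",
    "ex18-del236": "r.7977_8212del",
    "ex18-del309": "r.8023_8331del",
    "ex18-del298": "r.8034_8331del",
    "ex18-del164": "r.8168_8331del",
    "ex18-del157": "r.8175_8331del",
    "ex17-del151+ex18 skipping": "r.7826_8331del",
    "ivs17-ret58+ex18 skipping": "r.7977_8331delins7976+1_7976+58",
}


class TestEventApplication:
    @pytest.mark.parametrize("label", sorted(EXPECTED_DELTAS))
    def test_length_changes(self, mgbr2, catalog, label):
        t = catalog[label]
        fl_len = catalog["FL"].length_nt
        assert t.length_nt == fl_len + EXPECTED_DELTAS[label]
        assert t.net_delta_nt == EXPECTED_DELTAS[label]

    def test_delta_equals_sum_of_event_deltas(self, mgbr2):
        for label, events in EVENT_CATALOG.items():
            expected = sum(event_delta(mgbr2, e) for e in events)
            assert EXPECTED_DELTAS[label] == expected

    def test_canonical_transcript(self, catalog):
        fl = catalog["FL"]
        assert fl.label == "FL"
        assert fl.r_hgvs == "r.(=)"
        assert fl.is_canonical

    def test_composition_is_order_independent(self, mgbr2):
        a = SpliceEvent("alt_donor", "EX17", 151)
        b = SpliceEvent("exon_skip", "EX18")
        t1 = apply_splice_events(mgbr2, [a, b], label="x")
        t2 = apply_splice_events(mgbr2, [b, a], label="x")
        assert t1.pieces == t2.pieces
        assert t1.length_nt == t2.length_nt
        assert t1.r_hgvs == t2.r_hgvs

    def test_incompatible_events_rejected(self, mgbr2):
        with pytest.raises(CompositionError):
            apply_splice_events(mgbr2, [
                SpliceEvent("alt_acceptor", "EX17", 20),
                SpliceEvent("alt_acceptor", "EX17", 69)])
        with pytest.raises(CompositionError):
            apply_splice_events(mgbr2, [
                SpliceEvent("exon_skip", "EX17"),
                SpliceEvent("alt_donor", "EX17", 10)])

    def test_offset_beyond_exon_rejected(self, mgbr2):
        with pytest.raises(SpanError):
            apply_splice_events(mgbr2,
                                [SpliceEvent("alt_acceptor", "EX17", 400)])

    def test_length_equals_canonical_plus_deltas_random(self):
        rng = np.random.default_rng(3)
        for seed in range(15):
            sm = make_synthetic_minigene(SyntheticGeneSpec(
                n_exons=3, seed=seed))
            c = sm.construct
            fl = apply_splice_events(c)
            exon = c.exons[rng.integers(0, 3)].label
            k = int(rng.integers(1, 6))
            kind = ["exon_skip", "alt_acceptor", "alt_donor"][
                rng.integers(0, 3)]
            # intronic extensions need a neighbouring exon junction to be
            # describable, so restrict negative offsets to the middle exon
            offset = int(rng.choice([k, -k])) if exon == "EX2" else k
            ev = (SpliceEvent("exon_skip", exon) if kind == "exon_skip"
                  else SpliceEvent(kind, exon, offset))
            t = apply_splice_events(c, [ev])
            assert t.length_nt == fl.length_nt + event_delta(c, ev)


class TestRnaHgvs:
    @pytest.mark.parametrize("label", sorted(EXPECTED_RNA))
    def test_matches_published_style(self, catalog, label):
        assert catalog[label].r_hgvs == EXPECTED_RNA[label]

    def test_single_base_deletion_collapses_interval(self, catalog):
        # 1-nt acceptor shift is a single-position r. deletion
        assert catalog["ex17-del1"].r_hgvs == "r.7806del"

    def test_disjoint_alterations_join_in_one_allele(self, mgbr2):
        t = apply_splice_events(mgbr2, [
            SpliceEvent("alt_acceptor", "EX17", 20),
            SpliceEvent("exon_skip", "EX18")], label="x")
        assert t.r_hgvs == "r.[7806_7825del;7977_8331del]"

    def test_adjacent_exon_deletions_merge(self, mgbr2):
        t = apply_splice_events(mgbr2, [
            SpliceEvent("exon_skip", "EX17"),
            SpliceEvent("exon_skip", "EX18")], label="x")
        assert t.r_hgvs == "r.7806_8331del"

    def test_placeholder_has_no_description(self, mgbr2):
        with pytest.raises(UnsupportedDescriptionError):
            rna_hgvs(Transcript.placeholder("878nt", 878), mgbr2)

    @pytest.mark.parametrize("label", sorted(set(EXPECTED_RNA) - {"FL"}))
    def test_roundtrip_reproduces_retained_intervals(self, mgbr2, catalog,
                                                     label):
        t = catalog[label]
        dels, inss = parse_rna_hgvs(t.r_hgvs)
        expected_intervals, expected_ins = retained_intervals(t, mgbr2)
        assert apply_alterations(mgbr2, dels) == expected_intervals
        assert sorted(d for *_, d in inss) == expected_ins


class TestCandidateTable:
    def test_published_trio(self, mgbr2, primers):
        table = candidate_transcript_table(
            mgbr2,
            {"FL": frozenset(),
             "ex17 skipping": EVENT_CATALOG["ex17 skipping"],
             "ex18 skipping": EVENT_CATALOG["ex18 skipping"]},
            primers["RTBR2_ex16FW"], primers["RTpSAD-RV"])
        assert table.sizes == {"FL": 1012, "ex17 skipping": 841,
                               "ex18 skipping": 657}

    def test_one_nt_apart_candidates_are_distinct(self, mgbr2, primers):
        table = candidate_transcript_table(
            mgbr2, {"FL": frozenset(), "ex17-del1": EVENT_CATALOG["ex17-del1"]},
            primers["RTBR2_ex16FW"], primers["RTpSAD-RV"])
        assert table.sizes == {"FL": 1012, "ex17-del1": 1011}

    def test_full_catalog_sizes_are_unique(self, mgbr2, primers, catalog):
        table = candidate_transcript_table(
            mgbr2, dict(catalog), primers["RTBR2_ex16FW"],
            primers["RTpSAD-RV"])
        assert len(set(table.sizes.values())) == len(table.sizes)
        assert table.sizes["878nt"] == 878       # placeholder keeps its size
        assert "others" not in table.sizes       # size-less placeholder

    def test_primer_loss_flagged_unamplifiable(self, mgbr2, primers):
        table = candidate_transcript_table(
            mgbr2, {"FL": frozenset(),
                    "ex16 skipping": frozenset({SpliceEvent("exon_skip",
                                                            "EX16")})},
            primers["RTBR2_ex16FW"], primers["RTpSAD-RV"])
        assert table.unamplifiable == ("ex16 skipping",)
        assert "ex16 skipping" not in table.sizes

    def test_missing_canonical_rejected(self, mgbr2, primers):
        with pytest.raises(CatalogError):
            candidate_transcript_table(
                mgbr2, {"ex17 skipping": EVENT_CATALOG["ex17 skipping"]},
                primers["RTBR2_ex16FW"], primers["RTpSAD-RV"])

    def test_size_collision_rejected(self, mgbr2, primers):
        with pytest.raises(CatalogError):
            candidate_transcript_table(
                mgbr2,
                {"FL": frozenset(),
                 "a": frozenset({SpliceEvent("exon_skip", "EX19")}),
                 "b": frozenset({SpliceEvent("alt_donor", "EX18", 156)})},
                primers["RTBR2_ex16FW"], primers["RTpSAD-RV"])


def test_normalize_label():
    assert normalize_label("CT") == "FL"
    assert normalize_label("Full-length") == "FL"
    assert normalize_label("Ex17  Skipping") == "ex17 skipping"
    assert normalize_label("Ex18-del309") == "ex18-del309"
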