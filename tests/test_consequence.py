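"""Consequence annotation: frame arithmetic, PTC detection and p. strings,
checked against an independent brute-force translation oracle."""

import numpy as np
import pytest

from minisplice.consequence import (CodingContext, count_ptc_transcripts,
                                    deleted_residue_count, frame_status,
                                    mutant_cds, protein_consequence)
from minisplice.errors import AnnotationError, ContextError
from minisplice.simulate import SyntheticGeneSpec, make_synthetic_minigene
from minisplice.splice import SpliceEvent, Transcript, apply_splice_events

# ---------------------------------------------------------------------------
# independent oracle: naive event application + codon-table translation
# ---------------------------------------------------------------------------

_CODON = {}
_B = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
       "VVVVAAAADDEEGGGG")
for _i, (_a, _b, _c) in enumerate((a, b, c) for a in _B for b in _B
                                  for c in _B):
    _CODON[_a + _b + _c] = _AA[_i]


def oracle_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON[seq[i:i + 3]])
    return "".join(out)


def oracle_mutant_mrna(construct, ctx, event) -> str:
    """Build the mutant coding mRNA by direct slicing, independently of the
    engine's interval bookkeeping."""
    exons = construct.exons
    parts = []
    for i, exon in enumerate(exons):
        seq = exon.sequence
        if event.exon_label == exon.label:
            if event.kind == "exon_skip":
                continue
            if event.kind == "alt_acceptor":
                if event.offset > 0:
                    seq = seq[event.offset:]
                else:
                    intron = construct.intron_before(exon.label)
                    seq = intron.sequence[len(intron.sequence)
                                          + event.offset:] + seq
            elif event.kind == "alt_donor":
                if event.offset > 0:
                    seq = seq[:len(seq) - event.offset]
                else:
                    intron = construct.intron_after(exon.label)
                    seq = seq + intron.sequence[:-event.offset]
        parts.append(seq)
    return "".join(parts) + ctx.downstream_sequence


def oracle_ptc(construct, ctx, event) -> tuple[bool, int | None]:
    """(has_ptc, stop_codon_index) by naive translation of the mutant."""
    ref_body_len = len(ctx.cds_sequence) // 3 - 1
    mut = oracle_mutant_mrna(construct, ctx, event)
    prot = oracle_translate(mut)
    s = prot.find("*")
    if s < 0:
        return False, None
    delta = len(mut) - len(ctx.downstream_sequence) - len(ctx.cds_sequence)
    if delta % 3 == 0:
        expected = ref_body_len + delta // 3
        return (s < expected), (s + 1 if s < expected else None)
    return True, s + 1


def random_single_event(rng, construct) -> SpliceEvent:
    exons = construct.exons
    i = int(rng.integers(0, len(exons)))
    exon = exons[i]
    kind = ["exon_skip", "alt_acceptor", "alt_donor"][int(rng.integers(0, 3))]
    if kind == "exon_skip":
        return SpliceEvent("exon_skip", exon.label)
    k = int(rng.integers(1, min(30, exon.length - 1)))
    if bool(rng.integers(0, 2)):
        k = -k
        # intronic extension must have a neighbouring exon junction
        if kind == "alt_acceptor" and i == 0:
            k = -k
        if kind == "alt_donor" and i == len(exons) - 1:
            k = -k
    return SpliceEvent(kind, exon.label, k)


# ---------------------------------------------------------------------------
# frame arithmetic on the fixture catalog
# ---------------------------------------------------------------------------

class TestFrameStatus:
    @pytest.mark.parametrize("label,status", [
        ("ex17 skipping", "in_frame"), ("ex17-del69", "in_frame"),
        ("ex18-ins6", "in_frame"), ("ex18-del309", "in_frame"),
        ("ivs17-ret58+ex18 skipping", "in_frame"),
        ("ex18 skipping", "frameshift"), ("ex17-del1", "frameshift"),
        ("ex17-del20", "frameshift"), ("ivs16-ins8", "frameshift"),
        ("ex17-insAG", "frameshift"), ("ex18-del191", "frameshift"),
        ("ex18-del236", "frameshift"), ("ex18-del298", "frameshift"),
        ("ex18-del164", "frameshift"), ("ex18-del157", "frameshift"),
        ("ex17-del151+ex18 skipping", "frameshift"),
    ])
    def test_catalog_frames(self, catalog, label, status):
        assert frame_status(catalog[label])[0] == status

    @pytest.mark.parametrize("label,residues", [
        ("ex17 skipping", 57), ("ex17-del69", 23), ("ex18-del309", 103)])
    def test_deleted_residue_counts(self, catalog, label, residues):
        assert deleted_residue_count(catalog[label]) == residues

    def test_frameshift_has_no_residue_count(self, catalog):
        with pytest.raises(AnnotationError):
            deleted_residue_count(catalog["ex18 skipping"])

    def test_placeholder_not_annotatable(self):
        with pytest.raises(AnnotationError):
            frame_status(Transcript.placeholder("878nt", 878))


# ---------------------------------------------------------------------------
# translation-based annotation on synthetic sequence
# ---------------------------------------------------------------------------

class TestProteinConsequence:
    def test_canonical(self, synthetic_gene):
        c, ctx = synthetic_gene.construct, synthetic_gene.coding_context
        fl = apply_splice_events(c)
        q = protein_consequence(fl, ctx, c)
        assert q.consequence_class == "canonical"
        assert q.p_hgvs == "p.(=)"

    def test_codon_aligned_skip_matches_length_arithmetic(self):
        # exon lengths all multiples of 3: a skip is a clean residue block
        sm = make_synthetic_minigene(SyntheticGeneSpec(
            n_exons=3, exon_length_range=(60, 60), seed=2))
        c, ctx = sm.construct, sm.coding_context
        t = apply_splice_events(c, [SpliceEvent("exon_skip", "EX2")])
        q = protein_consequence(t, ctx, c)
        assert q.consequence_class == "in_frame_deletion"
        assert deleted_residue_count(t) == 20
        # the p. interval spans exactly that many residues
        import re
        m = re.match(r"p\.[A-Z](\d+)_[A-Z](\d+)del", q.p_hgvs)
        assert m and int(m.group(2)) - int(m.group(1)) + 1 == 20

    def test_missing_sequence_is_context_error(self, mgbr2):
        # the cohort construct ships without sequences: translation of a
        # retention event must fail loudly, not invent nucleotides
        t = apply_splice_events(mgbr2, [SpliceEvent("alt_donor", "EX17", -58),
                                        SpliceEvent("exon_skip", "EX18")],
                                label="ivs17-ret58+ex18 skipping")
        cds = "ATG" + "GGT" * 4000 + "TAA"
        with pytest.raises(ContextError):
            protein_consequence(t, CodingContext(cds), mgbr2)

    def test_fs_and_ptc_match_oracle_over_thousand_cases(self):
        rng = np.random.default_rng(123)
        checked = 0
        mismatches = []
        for seed in range(40):
            sm = make_synthetic_minigene(SyntheticGeneSpec(
                n_exons=2 + seed % 3, exon_length_range=(30, 90),
                intron_length_range=(30, 80), seed=seed))
            c, ctx = sm.construct, sm.coding_context
            for _ in range(25):
                ev = random_single_event(rng, c)
                t = apply_splice_events(c, [ev])
                q = protein_consequence(t, ctx, c)
                has_ptc, stop_idx = oracle_ptc(c, ctx, ev)
                got_ptc = q.consequence_class == "ptc_introducing"
                if got_ptc != has_ptc or (has_ptc and q.ptc != stop_idx):
                    mismatches.append((seed, ev, q, has_ptc, stop_idx))
                checked += 1
        assert checked >= 1000
        assert not mismatches, mismatches[:3]

    def test_count_ptc_transcripts_matches_oracle(self):
        rng = np.random.default_rng(7)
        sm = make_synthetic_minigene(SyntheticGeneSpec(n_exons=4, seed=11))
        c, ctx = sm.construct, sm.coding_context
        events = [random_single_event(rng, c) for _ in range(30)]
        transcripts = [apply_splice_events(c, [e]) for e in events]
        expected = sum(oracle_ptc(c, ctx, e)[0] for e in events)
        assert count_ptc_transcripts(transcripts, ctx, c) == expected

    def test_all_in_frame_set_counts_zero(self):
        sm = make_synthetic_minigene(SyntheticGeneSpec(
            n_exons=3, exon_length_range=(60, 60), seed=4))
        c, ctx = sm.construct, sm.coding_context
        transcripts = [
            apply_splice_events(c, [SpliceEvent("exon_skip", "EX2")]),
            apply_splice_events(c, [SpliceEvent("alt_acceptor", "EX2", 6)]),
            apply_splice_events(c, [SpliceEvent("alt_donor", "EX2", 9)]),
        ]
        assert count_ptc_transcripts(transcripts, ctx, c) == 0

    def test_placeholder_in_census_rejected(self, synthetic_gene):
        c, ctx = synthetic_gene.construct, synthetic_gene.coding_context
        with pytest.raises(AnnotationError):
            count_ptc_transcripts([Transcript.placeholder("x", 500)], ctx, c)

    def test_mutant_cds_applies_interval_edits(self, synthetic_gene):
        c, ctx = synthetic_gene.construct, synthetic_gene.coding_context
        ev = SpliceEvent("alt_acceptor", "EX2", 5)
        t = apply_splice_events(c, [ev])
        assert mutant_cds(t, ctx, c) == oracle_mutant_mrna(
            c, ctx, ev)[:-len(ctx.downstream_sequence)]
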