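"""Protein-level consequence annotation of aberrant transcripts.

Frame status is pure length arithmetic (net nucleotide change modulo 3);
everything beyond that — premature termination codons, p. descriptions —
comes from actually translating the mutant coding sequence against a
reference CDS and comparing the two proteins.  No NMD modelling is
applied: the assay this package interprets inhibits nonsense-mediated
decay pharmacologically, so PTC transcripts are observed at their true
abundance and degradation is out of model.

A transcript is ``ptc_introducing`` when its translation terminates at a
stop codon that truncates the reference protein — whether from a
frameshift or from in-frame neo-sequence (e.g. a retained intron carrying
a stop).  An in-frame deletion that simply shortens the protein and then
rejoins the reference reading is not a PTC, even though its stop codon
sits at a smaller index.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .construct import MinigeneConstruct
from .errors import AnnotationError, ContextError
from .splice import Transcript, _alterations

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CodingContext:
    """Reference CDS against which transcripts are annotated.

    ``cds_sequence`` runs from the start codon through the stop codon
    (length divisible by 3).  ``c_offset_of_first_modeled_base`` maps CDS
    index 0 to c. coordinate ``offset + 1``, allowing a partial CDS; with
    the default 0 the CDS begins at c.1.  ``downstream_sequence`` is the
    native 3' UTR continuation of the mRNA, read only when a frameshift
    carries translation past the reference stop.  Vector-exon sequence is
    never part of the context: transcripts are annotated against the
    native coding continuation, as on a full-length mRNA.
    """

    cds_sequence: str
    c_offset_of_first_modeled_base: int = 0
    downstream_sequence: str = ""

    def __post_init__(self) -> None:
        self.cds_sequence = self.cds_sequence.upper()
        if len(self.cds_sequence) % 3:
            raise ContextError("CDS length must be divisible by 3")
        if self.c_offset_of_first_modeled_base == 0:
            if not self.cds_sequence.startswith("ATG"):
                raise ContextError("full CDS must start with ATG")
            if self.cds_sequence[-3:] not in _STOPS:
                raise ContextError("full CDS must end with a stop codon")

    def index(self, c_base: int) -> int:
        i = c_base - 1 - self.c_offset_of_first_modeled_base
        if not 0 <= i < len(self.cds_sequence):
            raise ContextError(f"c.{c_base} outside the modeled CDS")
        return i

    @property
    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())


@dataclass
class Consequence:
    """Frame status, PTC position and protein-level description."""

    frame_status: str              # in_frame | frameshift
    net_delta_nt: int
    consequence_class: str
    ptc: int | None = None         # 1-based codon index of the premature stop
    p_hgvs: str | None = None


# ---------------------------------------------------------------------------
# frame arithmetic (length-only)
# ---------------------------------------------------------------------------

def frame_status(transcript: Transcript) -> tuple[str, int]:
    """``(in_frame|frameshift, net_delta_nt)`` from length arithmetic alone.

    Placeholder transcripts carry no structure and are not annotatable.
    """
    if transcript.is_placeholder or transcript.net_delta_nt is None:
        raise AnnotationError(
            f"transcript {transcript.label!r} is a size-only placeholder")
    delta = transcript.net_delta_nt
    return ("in_frame" if delta % 3 == 0 else "frameshift"), delta


def deleted_residue_count(transcript: Transcript) -> int:
    """Residues removed by an in-frame pure deletion: ``|delta| / 3``."""
    status, delta = frame_status(transcript)
    if status != "in_frame" or delta >= 0:
        raise AnnotationError(
            f"{transcript.label!r} is not an in-frame deletion "
            f"(delta {delta} nt)")
    if any(e.kind not in ("exon_skip", "alt_acceptor", "alt_donor")
           or (e.kind != "exon_skip" and e.offset < 0)
           for e in transcript.events):
        raise AnnotationError(
            f"{transcript.label!r} mixes insertions into the deletion")
    return -delta // 3


# ---------------------------------------------------------------------------
# translation-based annotation
# ---------------------------------------------------------------------------

def mutant_cds(transcript: Transcript, ctx: CodingContext,
               construct: MinigeneConstruct) -> str:
    """Apply a transcript's alterations to the reference CDS string.

    Deletions remove the corresponding c. interval; junction insertions
    splice in the retained intronic (or literal) nucleotides, taken from
    the construct's intron sequences when not given literally.  Raises
    :class:`ContextError` when a needed sequence is absent.
    """
    if transcript.is_placeholder:
        raise AnnotationError(
            f"placeholder {transcript.label!r} cannot be translated")
    dels, inss = _alterations(transcript, construct)
    edits: list[tuple[int, int, str]] = []   # (index, del_len, insert)
    for a, b in dels:
        edits.append((ctx.index(a), b - a + 1, ""))
    for left, _right, desc in inss:
        seq = _insertion_sequence(desc, transcript, construct)
        edits.append((ctx.index(left) + 1, 0, seq))
    out = ctx.cds_sequence
    for idx, ndel, ins in sorted(edits, reverse=True):
        out = out[:idx] + ins + out[idx + ndel:]
    return out


def _insertion_sequence(desc: str, transcript: Transcript,
                        construct: MinigeneConstruct) -> str:
    if set(desc) <= set("ACGU T"):
        return desc.replace("U", "T").replace(" ", "")
    # an intronic c. range such as "7806-8_7806-1"
    from .hgvs import parse_cpos
    a_txt, b_txt = desc.split("_")
    a, b = parse_cpos(a_txt), parse_cpos(b_txt)
    ia, oa = construct.resolve(a)
    ib, ob = construct.resolve(b)
    if ia != ib:
        raise ContextError(f"insertion range {desc} crosses segments")
    seg = construct.segments[ia]
    if seg.sequence is None:
        raise ContextError(
            f"intron {seg.label!r} has no sequence; cannot realise ins{desc}")
    return seg.sequence[oa:ob + 1]


def _translate(seq: str) -> str:
    usable = seq[:len(seq) - len(seq) % 3]
    return str(Seq(usable).translate())


def protein_consequence(transcript: Transcript, ctx: CodingContext,
                        construct: MinigeneConstruct) -> Consequence:
    """Translate the mutant CDS and describe the protein-level outcome.

    The changed region is normalised 3' (maximal common prefix, then
    maximal common suffix) before writing the p. description, per HGVS
    practice.  ``fs*N`` counts residues from the first altered residue to
    the new stop inclusive.
    """
    status, delta = frame_status(transcript)
    if transcript.is_canonical:
        return Consequence("in_frame", 0, "canonical", p_hgvs="p.(=)")

    ref = ctx.protein                      # ends with '*'
    ref_body = ref[:-1]
    mut_full = _translate(mutant_cds(transcript, ctx, construct)
                          + ctx.downstream_sequence)
    s = mut_full.find("*")                 # first stop of the mutant reading

    p = 0
    while p < min(len(ref), len(mut_full)) and ref[p] == mut_full[p]:
        p += 1

    if status == "frameshift":
        # the reading downstream of the first altered residue is novel; a
        # stop anywhere in it truncates the protein
        if s < 0:
            ref_aa = ref[p] if p < len(ref) else "?"
            mut_aa = mut_full[p] if p < len(mut_full) else "?"
            return Consequence(status, delta, "frameshift_no_stop",
                               p_hgvs=f"p.{ref_aa}{p + 1}{mut_aa}fs*?")
        ref_aa = ref[p] if p < len(ref) else "?"
        if s == p:
            return Consequence(status, delta, "ptc_introducing", ptc=p + 1,
                               p_hgvs=f"p.{ref_aa}{p + 1}*")
        return Consequence(status, delta, "ptc_introducing", ptc=s + 1,
                           p_hgvs=f"p.{ref_aa}{p + 1}{mut_full[p]}"
                                  f"fs*{s - p + 1}")

    # in-frame: net change is a multiple of 3 and the sequence downstream of
    # the altered interval is the reference in its reference frame, so the
    # reference stop survives; translation stops there unless neo-sequence
    # introduces a stop first.
    expected_stop = len(ref_body) + delta // 3
    if s < 0 or s > expected_stop:
        return Consequence(status, delta, "no_stop", p_hgvs="p.?")
    if s < expected_stop:
        ref_aa = ref[p] if p < len(ref) else "?"
        if s == p:
            return Consequence(status, delta, "ptc_introducing", ptc=p + 1,
                               p_hgvs=f"p.{ref_aa}{p + 1}*")
        return Consequence(status, delta, "ptc_introducing", ptc=s + 1,
                           p_hgvs=f"p.{ref_aa}{p + 1}{mut_full[p]}"
                                  f"fs*{s - p + 1}")

    mut_body = mut_full[:s]
    if mut_body == ref_body:
        return Consequence(status, delta, "synonymous", p_hgvs="p.(=)")
    # 3'-normalised changed region: maximal prefix, then maximal suffix
    p = min(p, len(mut_body), len(ref_body))
    q = 0
    while (q < min(len(ref_body), len(mut_body)) - p
           and ref_body[len(ref_body) - 1 - q] == mut_body[len(mut_body) - 1 - q]):
        q += 1
    mid_ref = ref_body[p:len(ref_body) - q]
    mid_mut = mut_body[p:len(mut_body) - q]

    if mid_mut == "" and mid_ref:
        k = len(mid_ref)
        if k == 1:
            p_str = f"p.{mid_ref}{p + 1}del"
        else:
            p_str = f"p.{mid_ref[0]}{p + 1}_{mid_ref[-1]}{p + k}del"
        return Consequence(status, delta, "in_frame_deletion", p_hgvs=p_str)

    if mid_ref == "" and mid_mut:
        left = ref_body[p - 1] if p > 0 else "?"
        right = ref_body[p] if p < len(ref_body) else "?"
        p_str = f"p.{left}{p}_{right}{p + 1}ins{mid_mut}"
        return Consequence(status, delta, "in_frame_delins", p_hgvs=p_str)

    if len(mid_ref) == 1 and len(mid_mut) == 1:
        cls = "nonsense_direct" if mid_mut == "*" else "missense"
        return Consequence(status, delta, cls,
                           p_hgvs=f"p.{mid_ref}{p + 1}{mid_mut}")

    p_str = (f"p.{mid_ref[0]}{p + 1}_{mid_ref[-1]}{p + len(mid_ref)}"
             f"delins{mid_mut}")
    return Consequence(status, delta, "in_frame_delins", p_hgvs=p_str)


def count_ptc_transcripts(transcripts, ctx: CodingContext,
                          construct: MinigeneConstruct) -> int:
    """Number of transcripts whose translation introduces a PTC.

    All transcripts must be structurally characterised; a placeholder in
    the list raises :class:`AnnotationError` rather than being silently
    skipped.
    """
    n = 0
    for t in transcripts:
        if t.is_placeholder:
            raise AnnotationError(
                f"placeholder {t.label!r} in PTC census input")
        c = protein_consequence(t, ctx, construct)
        if c.consequence_class == "ptc_introducing":
            n += 1
    return n
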