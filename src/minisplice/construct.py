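"""Splicing-reporter construct model.

A minigene is an ordered run of segments — a 5' vector exon, alternating
cloned introns/exons, and a 3' vector exon — transfected into cells so that
the splicing behaviour of the cloned exons can be read out by RT-PCR between
primers anchored in the vector exons (or in a cloned exon).  This module
represents that object, does amplicon-size arithmetic on it, designs the
microdeletion series used for enhancer mapping, and applies genomic
(DNA-level) variants to produce mutant constructs.

Cloned exons carry HGVS c. coordinate anchors so every variant and splicing
event can be described in the coordinates of the reference transcript.
Sequences are optional throughout: every size/frame computation is
length-only, and operations that genuinely need nucleotides say so by
raising :class:`~minisplice.errors.ContextError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .errors import (
    CoordinateError,
    DesignError,
    NoAmplificationError,
    SpanError,
    StructureError,
    UnsupportedDescriptionError,
)
from .hgvs import CPos, CVariant, parse_c_hgvs

VECTOR_EXON = "vector_exon"
EXON = "exon"
INTRON = "intron"
_ROLES = {VECTOR_EXON, EXON, INTRON}

#: splice-region window definitions (exonic bases from the boundary,
#: intronic bases from the boundary) used by :func:`derive_site_class`
_SPLICE_REGION_EXONIC = 3
_SPLICE_REGION_INTRONIC = 8


@dataclass
class Segment:
    """One construct segment: a vector exon, a cloned exon, or an intron.

    Exons may carry 1-based inclusive c. anchors (``c_start``/``c_end``);
    when present they must agree with ``length``.  ``edited`` marks segments
    whose length no longer matches the reference anchors because a genomic
    variant was applied; anchor consistency is then deliberately not
    enforced (the anchors keep naming reference coordinates).
    """

    role: str
    label: str
    length: int
    c_start: int | None = None
    c_end: int | None = None
    sequence: str | None = None
    edited: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise StructureError(f"unknown segment role {self.role!r}")
        if self.length < 1:
            raise StructureError(
                f"segment {self.label!r}: length must be >= 1, got {self.length}")
        if (self.c_start is None) != (self.c_end is None):
            raise CoordinateError(
                f"segment {self.label!r}: c_start and c_end must be given together")
        if self.c_start is not None and self.role != EXON:
            raise CoordinateError(
                f"segment {self.label!r}: only exons carry c. anchors")
        if self.c_start is not None and not self.edited:
            if self.c_end - self.c_start + 1 != self.length:
                raise CoordinateError(
                    f"segment {self.label!r}: c.{self.c_start}-{self.c_end} spans "
                    f"{self.c_end - self.c_start + 1} nt but length is {self.length}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise CoordinateError(
                    f"segment {self.label!r}: sequence length "
                    f"{len(self.sequence)} != declared length {self.length}")


@dataclass(frozen=True)
class PrimerSite:
    """A primer anchored in one segment.

    ``offset_from_segment_end`` is the number of nucleotides of the primer's
    own segment that end up inside the amplicon: for a forward primer the
    tail from the primer's 5' anchor to the segment's 3' end, for a reverse
    primer the head from the segment's 5' end to the primer's 5' anchor.
    Only this number (not the primer sequence) enters any size computation.
    """

    name: str
    segment_label: str
    offset_from_segment_end: int
    direction: str  # forward | reverse

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise StructureError(f"primer {self.name!r}: bad direction")
        if self.offset_from_segment_end < 1:
            raise StructureError(f"primer {self.name!r}: offset must be >= 1")


@dataclass
class GenomicVariant:
    """A DNA variant in construct (c.) coordinates, plus derived annotation.

    ``site_class`` is derived from position alone (see
    :func:`derive_site_class`); ``direct_coding_prediction`` is what the
    change would do to the protein if splicing were unaffected
    (nonsense/frameshift/missense/synonymous/intronic) and is supplied by
    the caller or a fixture, since it requires the reference protein.
    """

    c_hgvs: str
    edit_kind: str
    span: tuple[CPos, CPos]
    ref: str | None = None
    alt: str | None = None
    inserted_sequence: str | None = None
    site_class: str | None = None
    direct_coding_prediction: str | None = None

    @classmethod
    def from_hgvs(cls, text: str, *, direct_coding_prediction: str | None = None,
                  ) -> "GenomicVariant":
        cv: CVariant = parse_c_hgvs(text)
        return cls(c_hgvs=cv.c_hgvs, edit_kind=cv.edit_kind, span=cv.span,
                   ref=cv.ref, alt=cv.alt, inserted_sequence=cv.inserted_sequence,
                   direct_coding_prediction=direct_coding_prediction)

    @property
    def deleted_length(self) -> int:
        """Span length in nt for deletion-type edits (requires exonic or
        single-intron spans resolved by the construct; plain difference of
        like-anchored positions otherwise)."""
        a, b = self.span
        if a.base == b.base:
            return b.offset - a.offset + 1
        if a.offset == 0 and b.offset == 0:
            return b.base - a.base + 1
        raise CoordinateError(
            f"{self.c_hgvs}: span length needs construct context")


@dataclass
class MinigeneConstruct:
    """An ordered, validated splicing-reporter construct."""

    name: str
    segments: list[Segment]
    primers: list[PrimerSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = self.segments
        if len(segs) < 2 or segs[0].role != VECTOR_EXON or segs[-1].role != VECTOR_EXON:
            raise StructureError("first and last segments must be vector exons")
        inner = segs[1:-1]
        for a, b in zip(inner, inner[1:]):
            if a.role == EXON and b.role == EXON:
                raise StructureError(
                    f"adjacent exons {a.label!r}/{b.label!r} without an intron")
            if a.role == INTRON and b.role == INTRON:
                raise StructureError(
                    f"adjacent introns {a.label!r}/{b.label!r}: merge them")
            if VECTOR_EXON in (a.role, b.role):
                raise StructureError("vector exons only at the construct ends")
        labels = [s.label for s in segs]
        if len(set(labels)) != len(labels):
            raise StructureError("segment labels must be unique")
        anchored = [s for s in segs if s.c_start is not None]
        for a, b in zip(anchored, anchored[1:]):
            if b.c_start <= a.c_end:
                raise CoordinateError(
                    f"exon c. anchors not strictly increasing: "
                    f"{a.label} ends {a.c_end}, {b.label} starts {b.c_start}")
        for p in self.primers:
            seg = self.segment(p.segment_label)
            if p.offset_from_segment_end > seg.length:
                raise StructureError(
                    f"primer {p.name!r}: offset {p.offset_from_segment_end} exceeds "
                    f"segment {seg.label!r} length {seg.length}")

    # -- lookup helpers ---------------------------------------------------
    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise CoordinateError(f"no segment labelled {label!r} in {self.name}")

    def segment_index(self, label: str) -> int:
        for i, s in enumerate(self.segments):
            if s.label == label:
                return i
        raise CoordinateError(f"no segment labelled {label!r} in {self.name}")

    @property
    def exons(self) -> list[Segment]:
        return [s for s in self.segments if s.role == EXON]

    def primer(self, name: str) -> PrimerSite:
        for p in self.primers:
            if p.name == name:
                return p
        raise CoordinateError(f"no primer named {name!r} in {self.name}")

    def intron_before(self, exon_label: str) -> Segment | None:
        i = self.segment_index(exon_label)
        if i > 0 and self.segments[i - 1].role == INTRON:
            return self.segments[i - 1]
        return None

    def intron_after(self, exon_label: str) -> Segment | None:
        i = self.segment_index(exon_label)
        if i + 1 < len(self.segments) and self.segments[i + 1].role == INTRON:
            return self.segments[i + 1]
        return None

    def exon_containing(self, base: int) -> Segment:
        for s in self.exons:
            if s.c_start is not None and s.c_start <= base <= s.c_end:
                return s
        raise CoordinateError(f"c.{base} is not inside any anchored exon")

    # -- coordinate resolution --------------------------------------------
    def resolve(self, pos: CPos) -> tuple[int, int]:
        """Map a c. position to ``(segment_index, offset_within_segment)``.

        Intronic positions (offset != 0) must hang off the matching exon
        boundary: ``c.E+n`` off an exon end into the following intron,
        ``c.S-n`` off an exon start into the preceding intron.
        """
        if pos.offset == 0:
            exon = self.exon_containing(pos.base)
            return self.segment_index(exon.label), pos.base - exon.c_start
        exon = self.exon_containing(pos.base)
        if pos.offset > 0:
            if pos.base != exon.c_end:
                raise CoordinateError(
                    f"c.{pos}: '+' offsets must anchor at an exon 3' end")
            intron = self.intron_after(exon.label)
            if intron is None or pos.offset > intron.length:
                raise CoordinateError(f"c.{pos}: beyond intron after {exon.label}")
            return self.segment_index(intron.label), pos.offset - 1
        if pos.base != exon.c_start:
            raise CoordinateError(
                f"c.{pos}: '-' offsets must anchor at an exon 5' start")
        intron = self.intron_before(exon.label)
        if intron is None or -pos.offset > intron.length:
            raise CoordinateError(f"c.{pos}: beyond intron before {exon.label}")
        return self.segment_index(intron.label), intron.length + pos.offset

    def physical(self, pos: CPos) -> int:
        """Map a c. position to a 0-based index into the whole construct."""
        idx, off = self.resolve(pos)
        return sum(s.length for s in self.segments[:idx]) + off


# ---------------------------------------------------------------------------
# construction and arithmetic
# ---------------------------------------------------------------------------

def build_construct(spec: dict) -> MinigeneConstruct:
    """Build a validated construct from a structured description.

    ``spec`` is a mapping with ``name``, a ``segments`` list (each with
    ``role``, ``label``, ``length`` and, for exons, optional
    ``c_start``/``c_end`` and ``sequence``) and an optional ``primers``
    list.  Consecutive intron entries — the way shortened introns are
    printed, as two pieces around a gap — are merged into one intron
    (lengths summed, sequences concatenated, first label kept) so the
    resulting construct satisfies strict exon/intron alternation.
    """
    raw: list[Segment] = []
    for s in spec["segments"]:
        raw.append(Segment(role=s["role"], label=s["label"], length=int(s["length"]),
                           c_start=s.get("c_start"), c_end=s.get("c_end"),
                           sequence=s.get("sequence")))
    merged: list[Segment] = []
    for seg in raw:
        if merged and merged[-1].role == INTRON and seg.role == INTRON:
            prev = merged[-1]
            seq = None
            if prev.sequence is not None and seg.sequence is not None:
                seq = prev.sequence + seg.sequence
            merged[-1] = Segment(role=INTRON, label=prev.label,
                                 length=prev.length + seg.length, sequence=seq)
        else:
            merged.append(seg)
    primers = [PrimerSite(name=p["name"], segment_label=p["segment"],
                          offset_from_segment_end=int(p["offset_from_segment_end"]),
                          direction=p["direction"])
               for p in spec.get("primers", [])]
    return MinigeneConstruct(name=spec.get("name", "construct"),
                             segments=merged, primers=primers)


def total_insert_length(construct: MinigeneConstruct) -> int:
    """Total length of the cloned genomic insert (vector exons excluded)."""
    return sum(s.length for s in construct.segments if s.role != VECTOR_EXON)


def amplicon_length(transcript, fwd: PrimerSite, rev: PrimerSite) -> int:
    """RT-PCR product size for a primer pair on a (spliced) transcript.

    ``transcript`` is any object with an ordered ``pieces`` sequence of
    retained-segment intervals (see :class:`minisplice.splice.Transcript`).
    The size is the forward primer's retained tail, plus every retained
    piece between the primers, plus the reverse primer's retained head.
    A transcript that lost a primer's anchor raises
    :class:`NoAmplificationError` — deliberately a signal, not a number.
    """
    if transcript.pieces is None:
        raise NoAmplificationError(
            f"transcript {transcript.label!r} has no structure")
    pieces = transcript.pieces
    fwd_idx = fwd_contrib = None
    for i, p in enumerate(pieces):
        if p.source != fwd.segment_label:
            continue
        anchor = p.source_length - fwd.offset_from_segment_end
        if p.start <= anchor < p.end:
            fwd_idx, fwd_contrib = i, p.end - anchor
            break
    if fwd_idx is None:
        raise NoAmplificationError(
            f"forward primer {fwd.name!r} site absent from transcript "
            f"{transcript.label!r}")
    rev_idx = rev_contrib = None
    for i, p in enumerate(pieces):
        if p.source != rev.segment_label:
            continue
        anchor = rev.offset_from_segment_end - 1
        if p.start <= anchor < p.end:
            rev_idx, rev_contrib = i, anchor - p.start + 1
            break
    if rev_idx is None:
        raise NoAmplificationError(
            f"reverse primer {rev.name!r} site absent from transcript "
            f"{transcript.label!r}")
    if rev_idx < fwd_idx:
        raise NoAmplificationError(
            f"primer pair {fwd.name!r}/{rev.name!r} inverted on transcript")
    if fwd_idx == rev_idx:
        # both primers in one piece: distance inside that piece
        return rev_contrib - (pieces[fwd_idx].end - pieces[fwd_idx].start
                              - fwd_contrib)
    between = sum(p.length for p in pieces[fwd_idx + 1:rev_idx])
    return fwd_contrib + between + rev_contrib


# ---------------------------------------------------------------------------
# microdeletion design
# ---------------------------------------------------------------------------

def design_microdeletions(construct: MinigeneConstruct, exon_label: str,
                          window: int = 10,
                          targets="tiling") -> list[GenomicVariant]:
    """Design exonic microdeletions for splicing-enhancer mapping.

    Windows of ``window`` nt are tiled either across the whole exon interior
    (``targets="tiling"``) or across each requested c. interval (``targets``
    a list of ``(start, end)`` exonic coordinate pairs; overlapping windows
    arise naturally when requested intervals overlap).  The first two and
    the last three nucleotides of the exon are never touched — they belong
    to the acceptor/donor definitions — and any request that would reach
    them is a :class:`DesignError`.
    """
    exon = construct.segment(exon_label)
    if exon.role != EXON or exon.c_start is None:
        raise DesignError(f"{exon_label!r} is not an anchored exon")
    lo = exon.c_start + 2   # first allowed deleted base
    hi = exon.c_end - 3     # last allowed deleted base
    if window < 1 or window > hi - lo + 1:
        raise DesignError(
            f"window {window} does not fit inside {exon_label} minus "
            f"protected ends ({hi - lo + 1} nt available)")
    if targets == "tiling":
        intervals = [(lo, hi)]
    else:
        intervals = [(int(a), int(b)) for a, b in targets]
    out: list[GenomicVariant] = []
    for a, b in intervals:
        if a > b:
            raise DesignError(f"empty target interval c.{a}_{b}")
        if a < lo or b > hi:
            raise DesignError(
                f"target c.{a}_{b} touches the protected ends of {exon_label} "
                f"(allowed c.{lo}-{hi})")
        start = a
        while start + window - 1 <= b:
            out.append(GenomicVariant.from_hgvs(
                f"c.{start}_{start + window - 1}del"))
            start += window
    return out


# ---------------------------------------------------------------------------
# applying genomic variants
# ---------------------------------------------------------------------------

def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def apply_genomic_variant(construct: MinigeneConstruct,
                          variant: GenomicVariant) -> MinigeneConstruct:
    """Return a new construct with the DNA edit applied.

    Length bookkeeping is exact; segment sequences are edited when present.
    Exon c. anchors are kept as reference coordinates and the touched
    segments are flagged ``edited`` (their length may no longer match the
    anchor span).  Edits outside the covered region raise
    :class:`CoordinateError`.
    """
    segs = [replace(s) for s in construct.segments]
    starts = []
    acc = 0
    for s in segs:
        starts.append(acc)
        acc += s.length
    a_idx, a_off = construct.resolve(variant.span[0])
    b_idx, b_off = construct.resolve(variant.span[1])
    p0 = starts[a_idx] + a_off
    p1 = starts[b_idx] + b_off  # inclusive

    kind = variant.edit_kind
    if kind == "substitution":
        seg = segs[a_idx]
        if seg.sequence is not None:
            if variant.ref and seg.sequence[a_off] != variant.ref:
                warnings.warn(
                    f"{variant.c_hgvs}: reference base mismatch "
                    f"({seg.sequence[a_off]} in construct)")
            seg.sequence = (seg.sequence[:a_off] + variant.alt
                            + seg.sequence[a_off + 1:])
            seg.edited = True
    elif kind == "deletion":
        for i, s in enumerate(segs):
            cut = _overlap(starts[i], starts[i] + s.length, p0, p1 + 1)
            if not cut:
                continue
            if cut >= s.length:
                raise SpanError(
                    f"{variant.c_hgvs} would delete all of segment {s.label!r}")
            if s.sequence is not None:
                lo = max(p0 - starts[i], 0)
                s.sequence = s.sequence[:lo] + s.sequence[lo + cut:]
            s.length -= cut
            s.edited = True
    elif kind == "duplication":
        if a_idx != b_idx:
            raise UnsupportedDescriptionError(
                f"{variant.c_hgvs}: duplication across a segment boundary")
        seg = segs[a_idx]
        n = b_off - a_off + 1
        if seg.sequence is not None:
            seg.sequence = (seg.sequence[:b_off + 1]
                            + seg.sequence[a_off:b_off + 1]
                            + seg.sequence[b_off + 1:])
        seg.length += n
        seg.edited = True
    elif kind == "insertion":
        if variant.inserted_sequence is None:
            raise UnsupportedDescriptionError(
                f"{variant.c_hgvs}: insertion without a sequence")
        if p1 != p0 + 1:
            raise CoordinateError(
                f"{variant.c_hgvs}: insertion flanks are not adjacent")
        seg = segs[a_idx]
        n = len(variant.inserted_sequence)
        if seg.sequence is not None:
            seg.sequence = (seg.sequence[:a_off + 1] + variant.inserted_sequence
                            + seg.sequence[a_off + 1:])
        seg.length += n
        seg.edited = True
    elif kind == "delins":
        mid = apply_genomic_variant(
            construct, replace(variant, edit_kind="deletion"))
        seg = mid.segments[a_idx]
        n = len(variant.inserted_sequence or "")
        if seg.sequence is not None and variant.inserted_sequence:
            seg.sequence = (seg.sequence[:a_off] + variant.inserted_sequence
                            + seg.sequence[a_off:])
        seg.length += n
        seg.edited = True
        segs = mid.segments
    else:
        raise UnsupportedDescriptionError(f"unknown edit kind {kind!r}")
    return MinigeneConstruct(name=f"{construct.name}[{variant.c_hgvs}]",
                             segments=segs, primers=list(construct.primers))


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def derive_site_class(construct: MinigeneConstruct,
                      variant: GenomicVariant) -> str:
    """Classify a variant's position relative to the splice sites.

    ``canonical_dinucleotide`` — the edit alters or duplicates an intronic
    ±1/±2 position of an annotated donor or acceptor; ``splice_region`` —
    within the last/first 3 exonic or 3–8 intronic bases of a boundary;
    otherwise plain ``exonic`` or ``intronic``.
    """
    a, b = variant.span
    positions: list[CPos] = []
    if variant.edit_kind in ("substitution",):
        positions = [a]
    else:
        positions = _span_positions(construct, a, b)

    classes = {_classify_position(construct, p) for p in positions}
    for c in ("canonical_dinucleotide", "splice_region", "exonic", "intronic"):
        if c in classes:
            return c
    return "intronic"


def _span_positions(construct: MinigeneConstruct, a: CPos, b: CPos) -> list[CPos]:
    """Enumerate the c. positions inside an inclusive span."""
    ia, oa = construct.resolve(a)
    ib, ob = construct.resolve(b)
    out: list[CPos] = []
    for idx in range(ia, ib + 1):
        seg = construct.segments[idx]
        lo = oa if idx == ia else 0
        hi = ob if idx == ib else seg.length - 1
        for off in range(lo, hi + 1):
            out.append(_cpos_at(construct, idx, off))
    return out


def _cpos_at(construct: MinigeneConstruct, idx: int, off: int) -> CPos:
    seg = construct.segments[idx]
    if seg.role == EXON and seg.c_start is not None:
        return CPos(seg.c_start + off)
    if seg.role == INTRON:
        prev = construct.segments[idx - 1] if idx > 0 else None
        nxt = construct.segments[idx + 1] if idx + 1 < len(construct.segments) else None
        # prefer the nearer exon boundary, matching HGVS practice
        if prev is not None and prev.role == EXON and prev.c_start is not None \
                and off < seg.length - off:
            return CPos(prev.c_end, off + 1)
        if nxt is not None and nxt.role == EXON and nxt.c_start is not None:
            return CPos(nxt.c_start, off - seg.length)
        if prev is not None and prev.role == EXON and prev.c_start is not None:
            return CPos(prev.c_end, off + 1)
    raise CoordinateError(f"position in segment {seg.label!r} has no c. name")


def _classify_position(construct: MinigeneConstruct, p: CPos) -> str:
    if p.offset != 0:
        d = abs(p.offset)
        if d <= 2:
            return "canonical_dinucleotide"
        if d <= _SPLICE_REGION_INTRONIC:
            return "splice_region"
        return "intronic"
    exon = construct.exon_containing(p.base)
    if (p.base - exon.c_start < _SPLICE_REGION_EXONIC
            or exon.c_end - p.base < _SPLICE_REGION_EXONIC):
        return "splice_region"
    return "exonic"


def variant_region(construct: MinigeneConstruct, variant: GenomicVariant) -> str:
    """Name the exon region a variant belongs to, e.g. ``"ex17"``.

    Intronic positions attach to the exon their HGVS anchor names, so
    ``c.7976+1`` is an ex17-region variant and ``c.7977-7`` an ex18-region
    one.
    """
    exon = construct.exon_containing(variant.span[0].base)
    digits = "".join(ch for ch in exon.label if ch.isdigit())
    return f"ex{digits}" if digits else exon.label.lower()
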