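"""Splice-event engine: from events to transcript structures and HGVS r.

Events are structural, described as offsets from annotated exon boundaries:
an exon skip, an alternative acceptor/donor shifted *into* the exon
(positive offset — exonic deletion) or *into* the flanking intron (negative
offset — intronic insertion), a partial intron retention, or an exonic
insertion.  Whether an alternative site is "cryptic" or "de novo" is
metadata the engine does not need: transcript names such as ``ex18-del309``
are pure offset descriptions.

Applying an event set to a construct yields a :class:`Transcript`: the
ordered retained intervals of the mature mRNA (vector exon – exons – vector
exon), its size, a conventional label and an HGVS r. description.
Uncharacterised species seen in electropherograms ("others", a lone 878-nt
product) are representable as size-only placeholders so quantification
never has to drop observed signal mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .construct import EXON, MinigeneConstruct, PrimerSite, amplicon_length
from .errors import (
    CatalogError,
    CompositionError,
    NoAmplificationError,
    SpanError,
    UnsupportedDescriptionError,
)
from .hgvs import CPos, format_interval

EXON_SKIP = "exon_skip"
ALT_ACCEPTOR = "alt_acceptor"
ALT_DONOR = "alt_donor"
INTRON_RETENTION = "intron_retention_partial"
EXONIC_INSERTION = "exonic_insertion"
_KINDS = {EXON_SKIP, ALT_ACCEPTOR, ALT_DONOR, INTRON_RETENTION, EXONIC_INSERTION}


@dataclass(frozen=True)
class SpliceEvent:
    """One splicing alteration anchored at an exon.

    ``offset`` for alternative sites: positive = shift into the exon
    (deletes the exon's first/last ``offset`` nt), negative = shift into
    the intron (appends ``|offset|`` intronic nt).  ``retained_span`` (for
    partial intron retention) is an inclusive pair of intronic c.
    positions.  ``inserted_sequence`` optionally records the inserted
    nucleotides when they are known (e.g. an AG acceptor dinucleotide).
    """

    kind: str
    exon_label: str
    offset: int = 0
    retained_span: tuple[CPos, CPos] | None = None
    inserted_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise CompositionError(f"unknown event kind {self.kind!r}")
        if self.kind == EXON_SKIP and self.offset != 0:
            raise CompositionError("exon_skip takes no offset")
        if self.kind in (ALT_ACCEPTOR, ALT_DONOR) and self.offset == 0:
            raise CompositionError(f"{self.kind} requires a nonzero offset")
        if self.kind == INTRON_RETENTION and self.retained_span is None:
            raise CompositionError("intron retention requires retained_span")
        if self.kind == EXONIC_INSERTION and not self.inserted_sequence:
            raise CompositionError("exonic_insertion requires a sequence")


@dataclass(frozen=True)
class Piece:
    """A retained interval of one source segment (0-based half-open)."""

    source: str          # segment label, or a synthetic label for insertions
    start: int
    end: int
    kind: str            # exon | vector_exon | intron | insertion
    source_length: int   # full length of the source segment
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """A (possibly aberrant) mature transcript of the reporter minigene.

    ``pieces`` is ``None`` for size-only placeholders (uncharacterised
    species); every structural operation rejects those loudly.
    ``net_delta_nt`` is the signed length change versus the canonical
    transcript.
    """

    label: str
    length_nt: int
    events: frozenset[SpliceEvent] = frozenset()
    pieces: tuple[Piece, ...] | None = None
    r_hgvs: str | None = None
    net_delta_nt: int | None = 0

    @classmethod
    def placeholder(cls, label: str, length_nt: int | None = None) -> "Transcript":
        """A species observed by size only (no structural characterisation)."""
        return cls(label=label, length_nt=length_nt or 0, events=frozenset(),
                   pieces=None, r_hgvs=None, net_delta_nt=None)

    @property
    def is_placeholder(self) -> bool:
        return self.pieces is None

    @property
    def is_canonical(self) -> bool:
        return self.pieces is not None and not self.events


# ---------------------------------------------------------------------------
# label conventions
# ---------------------------------------------------------------------------

_CANONICAL_ALIASES = {"ct", "fl", "full-length", "full length", "canonical"}


def normalize_label(label: str) -> str:
    """Normalise a transcript label to the package's byte-stable convention.

    Lowercases, collapses whitespace, and maps the canonical-transcript
    aliases (``CT``, ``full-length`` …) to ``FL`` so fixtures and reports
    compare byte-for-byte.
    """
    s = re.sub(r"\s+", " ", label.strip().lower())
    if s in _CANONICAL_ALIASES:
        return "FL"
    return s


def _exon_number(exon_label: str) -> str:
    digits = "".join(ch for ch in exon_label if ch.isdigit())
    return digits or exon_label.lower()


def _event_label(event: SpliceEvent) -> str:
    n = _exon_number(event.exon_label)
    if event.kind == EXON_SKIP:
        return f"ex{n} skipping"
    if event.kind in (ALT_ACCEPTOR, ALT_DONOR):
        if event.offset > 0:
            return f"ex{n}-del{event.offset}"
        if event.inserted_sequence and len(event.inserted_sequence) <= 3:
            return f"ex{n}-ins{event.inserted_sequence}"
        return f"ex{n}-ins{-event.offset}"
    if event.kind == INTRON_RETENTION:
        a, b = event.retained_span
        return f"ivs-ret{b.offset - a.offset + 1}" if a.base == b.base \
            else f"ivs-ret({a}_{b})"
    return f"ex{n}-ins{event.inserted_sequence}"


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------

def event_delta(construct: MinigeneConstruct, event: SpliceEvent) -> int:
    """Signed transcript-length change caused by one event."""
    exon = construct.segment(event.exon_label)
    if event.kind == EXON_SKIP:
        return -exon.length
    if event.kind in (ALT_ACCEPTOR, ALT_DONOR):
        if event.offset > 0 and event.offset > exon.length:
            raise SpanError(
                f"{event.kind} offset {event.offset} exceeds "
                f"{event.exon_label} length {exon.length}")
        return -event.offset
    if event.kind == INTRON_RETENTION:
        a, b = event.retained_span
        pa, pb = construct.physical(a), construct.physical(b)
        if pb < pa:
            raise SpanError(f"empty retention span {a}_{b}")
        return pb - pa + 1
    return len(event.inserted_sequence)


def _validate_events(construct: MinigeneConstruct,
                     events: frozenset[SpliceEvent]) -> None:
    by_exon: dict[str, list[SpliceEvent]] = {}
    for e in events:
        construct.segment(e.exon_label)  # raises if absent
        by_exon.setdefault(e.exon_label, []).append(e)
    for label, evs in by_exon.items():
        kinds = [e.kind for e in evs]
        if EXON_SKIP in kinds and len(evs) > 1:
            raise CompositionError(
                f"exon_skip on {label} excludes other events on that exon")
        for side in (ALT_ACCEPTOR, ALT_DONOR):
            if kinds.count(side) > 1:
                raise CompositionError(
                    f"two {side} events on {label} cannot be composed")


def apply_splice_events(construct: MinigeneConstruct,
                        events=frozenset(),
                        label: str | None = None) -> Transcript:
    """Apply a compatible set of splicing events; empty set gives ``FL``.

    Pieces are assembled in construct order: 5' vector exon, each retained
    (possibly trimmed/extended) exon with any intronic additions, the 3'
    vector exon.  The label defaults to the field convention
    (``ex17 skipping``, ``ex18-del309``, joined with ``+`` for composites).
    """
    events = frozenset(events)
    _validate_events(construct, events)
    for e in events:
        event_delta(construct, e)  # span validation

    def seg_piece(seg, start, end):
        seq = seg.sequence[start:end] if seg.sequence is not None else None
        return Piece(source=seg.label, start=start, end=end, kind=seg.role,
                     source_length=seg.length, sequence=seq)

    pieces: list[Piece] = []
    ordered_events: list[SpliceEvent] = []
    segs = construct.segments
    pieces.append(seg_piece(segs[0], 0, segs[0].length))
    for seg in segs[1:-1]:
        if seg.role != EXON:
            continue
        evs = sorted((e for e in events if e.exon_label == seg.label),
                     key=lambda e: (e.kind != ALT_ACCEPTOR, e.kind != EXON_SKIP))
        skip = any(e.kind == EXON_SKIP for e in evs)
        acc = next((e for e in evs if e.kind == ALT_ACCEPTOR), None)
        don = next((e for e in evs if e.kind == ALT_DONOR), None)
        ins = [e for e in evs if e.kind == EXONIC_INSERTION]
        ret = [e for e in evs if e.kind == INTRON_RETENTION]
        ordered_events.extend(evs)

        if acc is not None and acc.offset < 0:
            intron = construct.intron_before(seg.label)
            k = -acc.offset
            seq = acc.inserted_sequence
            if seq is None and intron.sequence is not None:
                seq = intron.sequence[intron.length - k:]
            pieces.append(Piece(source=intron.label, start=intron.length - k,
                                end=intron.length, kind="intron",
                                source_length=intron.length, sequence=seq))
        if not skip:
            a = acc.offset if (acc is not None and acc.offset > 0) else 0
            d = don.offset if (don is not None and don.offset > 0) else 0
            if a + d >= seg.length:
                raise SpanError(
                    f"alternative sites remove all of {seg.label}")
            pieces.append(seg_piece(seg, a, seg.length - d))
            for e in ins:
                pieces.append(Piece(source=f"ins@{seg.label}", start=0,
                                    end=len(e.inserted_sequence),
                                    kind="insertion",
                                    source_length=len(e.inserted_sequence),
                                    sequence=e.inserted_sequence))
        if don is not None and don.offset < 0:
            intron = construct.intron_after(seg.label)
            k = -don.offset
            if k > intron.length:
                raise SpanError(f"donor shift {k} exceeds intron "
                                f"{intron.label} length")
            seq = don.inserted_sequence
            if seq is None and intron.sequence is not None:
                seq = intron.sequence[:k]
            pieces.append(Piece(source=intron.label, start=0, end=k,
                                kind="intron", source_length=intron.length,
                                sequence=seq))
        for e in ret:
            a, b = e.retained_span
            ia, oa = construct.resolve(a)
            ib, ob = construct.resolve(b)
            if ia != ib:
                raise SpanError(f"retention span {a}_{b} crosses segments")
            intron = construct.segments[ia]
            seq = (intron.sequence[oa:ob + 1]
                   if intron.sequence is not None else e.inserted_sequence)
            pieces.append(Piece(source=intron.label, start=oa, end=ob + 1,
                                kind="intron", source_length=intron.length,
                                sequence=seq))
    pieces.append(seg_piece(segs[-1], 0, segs[-1].length))

    length = sum(p.length for p in pieces)
    delta = sum(event_delta(construct, e) for e in events)
    if label is None:
        label = "FL" if not events else "+".join(
            _event_label(e) for e in ordered_events)
    t = Transcript(label=label, length_nt=length, events=events,
                   pieces=tuple(pieces), net_delta_nt=delta)
    return Transcript(label=t.label, length_nt=t.length_nt, events=t.events,
                      pieces=t.pieces, net_delta_nt=t.net_delta_nt,
                      r_hgvs=rna_hgvs(t, construct))


# ---------------------------------------------------------------------------
# HGVS r. descriptions
# ---------------------------------------------------------------------------

def _mrna_ordinal(construct: MinigeneConstruct, base: int) -> int:
    """1-based position of an exonic c. base within the spliced mRNA."""
    pos = 0
    for exon in construct.exons:
        if exon.c_start <= base <= exon.c_end:
            return pos + (base - exon.c_start) + 1
        pos += exon.length
    raise UnsupportedDescriptionError(f"c.{base} not exonic")


def _alterations(transcript: Transcript,
                 construct: MinigeneConstruct):
    """Decompose an event set into c.-space deletions and junction insertions.

    Returns ``(deletions, insertions)`` where deletions are inclusive
    ``(c_from, c_to)`` integer pairs merged across mRNA-adjacent exon
    boundaries, and insertions are ``(c_left, c_right, description)`` with
    the description either the literal sequence or an intronic c. range
    such as ``7806-8_7806-1``.
    """
    dels: list[tuple[int, int]] = []
    inss: list[tuple[int, int, str]] = []
    exon_list = construct.exons

    def prev_exon(exon):
        i = exon_list.index(exon)
        return exon_list[i - 1] if i > 0 else None

    def next_exon(exon):
        i = exon_list.index(exon)
        return exon_list[i + 1] if i + 1 < len(exon_list) else None

    for e in sorted(transcript.events,
                    key=lambda e: construct.segment(e.exon_label).c_start or 0):
        exon = construct.segment(e.exon_label)
        if e.kind == EXON_SKIP:
            dels.append((exon.c_start, exon.c_end))
        elif e.kind == ALT_ACCEPTOR:
            if e.offset > 0:
                dels.append((exon.c_start, exon.c_start + e.offset - 1))
            else:
                k = -e.offset
                left = prev_exon(exon)
                if left is None:
                    raise UnsupportedDescriptionError(
                        f"no upstream exon for acceptor extension on {exon.label}")
                desc = (e.inserted_sequence if e.inserted_sequence
                        else f"{exon.c_start}-{k}_{exon.c_start}-1")
                inss.append((left.c_end, exon.c_start, desc))
        elif e.kind == ALT_DONOR:
            if e.offset > 0:
                dels.append((exon.c_end - e.offset + 1, exon.c_end))
            else:
                k = -e.offset
                right = next_exon(exon)
                if right is None:
                    raise UnsupportedDescriptionError(
                        f"no downstream exon for donor extension on {exon.label}")
                desc = (e.inserted_sequence if e.inserted_sequence
                        else f"{exon.c_end}+1_{exon.c_end}+{k}")
                inss.append((exon.c_end, right.c_start, desc))
        elif e.kind == INTRON_RETENTION:
            a, b = e.retained_span
            right = next_exon(exon) if a.offset > 0 else exon
            left = exon if a.offset > 0 else prev_exon(exon)
            inss.append((left.c_end, right.c_start, f"{a}_{b}"))
        else:  # exonic insertion: not expressible without a fixed point
            raise UnsupportedDescriptionError(
                "exonic_insertion has no r. description without coordinates")

    dels.sort()
    merged: list[tuple[int, int]] = []
    for d in dels:
        if merged and _mrna_ordinal(construct, d[0]) == \
                _mrna_ordinal(construct, merged[-1][1]) + 1:
            merged[-1] = (merged[-1][0], d[1])
        else:
            merged.append(d)
    return merged, inss


def rna_hgvs(transcript: Transcript, construct: MinigeneConstruct) -> str:
    """HGVS r. description of a transcript's alterations.

    Exon skips and exonic alternative-site deletions merge into contiguous
    ``r.X_Ydel`` runs when adjacent in the spliced mRNA; intronic
    extensions/retentions become ``ins`` (or ``delins`` when flanking a
    deletion).  Multiple disjoint alterations are joined in one allele as
    ``r.[a;b]``.  Placeholders have no description and raise
    :class:`UnsupportedDescriptionError`.
    """
    if transcript.is_placeholder:
        raise UnsupportedDescriptionError(
            f"placeholder transcript {transcript.label!r} has no r. description")
    if not transcript.events:
        return "r.(=)"
    dels, inss = _alterations(transcript, construct)

    parts: list[str] = []
    used_ins = [False] * len(inss)
    for a, b in dels:
        attached = None
        for i, (l, r, desc) in enumerate(inss):
            if used_ins[i]:
                continue
            # insertion at a junction flanking this deletion -> delins
            if r == a or l == b:
                attached, used_ins[i] = desc, True
                break
        span = format_interval(CPos(a), CPos(b))
        parts.append(f"{span}delins{attached}" if attached else f"{span}del")
    for i, (l, r, desc) in enumerate(inss):
        if not used_ins[i]:
            parts.append(f"{l}_{r}ins{desc}")
    if len(parts) == 1:
        return f"r.{parts[0]}"
    return "r.[" + ";".join(parts) + "]"


# -- r. round-trip support ---------------------------------------------------

_R_DEL_RE = re.compile(r"^(?P<a>\d+)(?:_(?P<b>\d+))?del$")
_R_INS_RE = re.compile(r"^(?P<l>\d+)_(?P<r>\d+)ins(?P<desc>\S+)$")
_R_DELINS_RE = re.compile(r"^(?P<a>\d+)(?:_(?P<b>\d+))?delins(?P<desc>\S+)$")


def parse_rna_hgvs(text: str):
    """Parse an r. string of this module's dialect back into alterations.

    Returns ``(deletions, insertions)`` in the same shape
    :func:`rna_hgvs` was built from, enabling round-trip checks.  Junction
    coordinates for parsed insertions/delins are recovered as written.
    """
    s = text.strip()
    if s in ("r.(=)", "r.="):
        return [], []
    if not s.startswith("r."):
        raise UnsupportedDescriptionError(f"not an r. description: {text!r}")
    body = s[2:]
    if body.startswith("[") and body.endswith("]"):
        items = body[1:-1].split(";")
    else:
        items = [body]
    dels: list[tuple[int, int]] = []
    inss: list[tuple[int | None, int | None, str]] = []
    for it in items:
        it = it.strip()
        if (m := _R_DELINS_RE.match(it)) is not None:
            a = int(m.group("a"))
            b = int(m.group("b") or a)
            dels.append((a, b))
            inss.append((None, None, m.group("desc")))
        elif (m := _R_DEL_RE.match(it)) is not None:
            a = int(m.group("a"))
            dels.append((a, int(m.group("b") or a)))
        elif (m := _R_INS_RE.match(it)) is not None:
            inss.append((int(m.group("l")), int(m.group("r")), m.group("desc")))
        else:
            raise UnsupportedDescriptionError(f"unsupported r. item {it!r}")
    return dels, inss


def retained_intervals(transcript: Transcript,
                       construct: MinigeneConstruct):
    """Exonic c. intervals retained in a transcript plus insertion descs.

    The canonical mRNA is the ordered exon intervals; applying the
    transcript's deletions leaves the retained intervals.  Used by the
    round-trip property: parsing the emitted r. string and applying it must
    reproduce this exact structure.
    """
    dels, inss = _alterations(transcript, construct)
    return apply_alterations(construct, dels), sorted(d for *_, d in inss)


def apply_alterations(construct: MinigeneConstruct,
                      dels: list[tuple[int, int]]):
    """Subtract c.-space deletions from the canonical exon intervals."""
    intervals = [(e.c_start, e.c_end) for e in construct.exons]
    for a, b in sorted(dels):
        out = []
        for lo, hi in intervals:
            if b < lo or a > hi:
                out.append((lo, hi))
                continue
            if lo < a:
                out.append((lo, a - 1))
            if b < hi:
                out.append((b + 1, hi))
        intervals = out
    return intervals


# ---------------------------------------------------------------------------
# candidate transcript tables
# ---------------------------------------------------------------------------

@dataclass
class CandidateTable:
    """Expected amplicon size per candidate transcript for one primer pair."""

    sizes: dict[str, int]
    transcripts: dict[str, Transcript]
    unamplifiable: tuple[str, ...] = ()

    def __getitem__(self, label: str) -> int:
        return self.sizes[label]


def candidate_transcript_table(construct: MinigeneConstruct,
                               catalog: dict,
                               fwd: PrimerSite,
                               rev: PrimerSite) -> CandidateTable:
    """Expected amplicon sizes for a catalog of candidate event sets.

    ``catalog`` maps label -> event set (the canonical empty set must be
    present); values may also be ready-made :class:`Transcript` objects,
    including size-only placeholders (kept at their observed size).
    Transcripts that lose a primer are excluded and flagged unamplifiable.
    """
    if not any((isinstance(v, Transcript) and v.is_canonical)
               or (not isinstance(v, Transcript) and not v)
               for v in catalog.values()):
        raise CatalogError("catalog must include the canonical (empty) event set")
    sizes: dict[str, int] = {}
    transcripts: dict[str, Transcript] = {}
    unamp: list[str] = []
    for label, value in catalog.items():
        if label in transcripts:
            raise CatalogError(f"duplicate candidate label {label!r}")
        t = value if isinstance(value, Transcript) else \
            apply_splice_events(construct, value, label=label)
        transcripts[label] = t
        if t.is_placeholder:
            if t.length_nt:
                sizes[label] = t.length_nt
            continue
        try:
            sizes[label] = amplicon_length(t, fwd, rev)
        except NoAmplificationError:
            unamp.append(label)
    if len(set(sizes.values())) != len(sizes):
        dupes = sorted(s for s in sizes.values()
                       if list(sizes.values()).count(s) > 1)
        raise CatalogError(f"candidate sizes collide: {dupes}")
    return CandidateTable(sizes=sizes, transcripts=transcripts,
                          unamplifiable=tuple(unamp))
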