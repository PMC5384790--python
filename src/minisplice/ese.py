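"""Exonic splicing enhancer scanning with position-weight matrices.

SR-protein binding motifs (SF2/ASF, SC35, SRp40, ...) are short degenerate
exonic elements; a PWM assigns each window the sum of per-position,
per-base scores and windows at or above the matrix threshold are reported.
Intersecting hits with a microdeletion series localises the enhancers a
spliceogenic deletion removed — the in-silico half of functional ESE
mapping.

Matrices ship as editable YAML; the packaged defaults are illustrative
consensus-derived matrices (see ``data/pwms_synthetic.yaml``), and any
published matrix set (e.g. the ESEfinder matrices) can be dropped into the
same format.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .construct import GenomicVariant, MinigeneConstruct
from .errors import AlphabetError, ConfigurationError, ContextError

_BASES = "ACGT"


@dataclass
class PWM:
    """A position-weight matrix: per-position score per base, plus the
    minimal reportable score."""

    name: str
    matrix: list[dict[str, float]]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.matrix) < 6:
            raise ConfigurationError(
                f"PWM {self.name!r}: width must be >= 6, got {len(self.matrix)}")
        for col in self.matrix:
            if set(col) != set(_BASES):
                raise ConfigurationError(
                    f"PWM {self.name!r}: each column needs scores for A/C/G/T")

    @property
    def width(self) -> int:
        return len(self.matrix)

    def score(self, window: str) -> float:
        if len(window) != self.width:
            raise ConfigurationError(
                f"window length {len(window)} != PWM width {self.width}")
        return sum(col[base] for col, base in zip(self.matrix, window))

    @classmethod
    def from_consensus(cls, name: str, sequences: list[str],
                       match: float = 1.0, mismatch: float = -1.0,
                       threshold: float | None = None) -> "PWM":
        """Build a degenerate matrix from example binding sequences: each
        position scores ``match`` for bases seen there and ``mismatch``
        otherwise.  Default threshold admits exactly the examples
        (width * match)."""
        widths = {len(s) for s in sequences}
        if len(widths) != 1:
            raise ConfigurationError("consensus sequences differ in length")
        w = widths.pop()
        matrix = []
        for i in range(w):
            seen = {s[i].upper() for s in sequences}
            matrix.append({b: (match if b in seen else mismatch)
                           for b in _BASES})
        return cls(name=name, matrix=matrix,
                   threshold=w * match if threshold is None else threshold)


@dataclass(frozen=True)
class MotifHit:
    """One reported PWM hit, in c. coordinates (inclusive)."""

    pwm_name: str
    c_start: int
    c_end: int
    sequence: str
    score: float


def pwm_scan(sequence: str, pwms: list[PWM], c_anchor: int = 1,
             ) -> list[MotifHit]:
    """Scan a sequence with each PWM; report windows scoring >= threshold.

    ``c_anchor`` is the c. coordinate of the sequence's first base, so hit
    coordinates line up with variant and deletion coordinates.  Hits are
    sorted by position then score.  Any non-ACGT character (including N)
    is an :class:`AlphabetError` — degenerate windows are not scored.
    """
    seq = sequence.upper()
    if set(seq) - set(_BASES):
        raise AlphabetError(
            f"sequence contains non-ACGT characters: "
            f"{sorted(set(seq) - set(_BASES))}")
    hits: list[MotifHit] = []
    for pwm in pwms:
        if len(seq) < pwm.width:
            continue
        for i in range(len(seq) - pwm.width + 1):
            window = seq[i:i + pwm.width]
            s = pwm.score(window)
            if s >= pwm.threshold:
                hits.append(MotifHit(pwm_name=pwm.name, c_start=c_anchor + i,
                                     c_end=c_anchor + i + pwm.width - 1,
                                     sequence=window, score=s))
    hits.sort(key=lambda h: (h.c_start, -h.score, h.pwm_name))
    return hits


def scan_exon(construct: MinigeneConstruct, exon_label: str,
              pwms: list[PWM], include_flanking_introns: bool = False,
              ) -> list[MotifHit]:
    """Scan one exon's sequence (optionally with its flanking introns).

    Exon-only by default; intronic scanning is an explicit opt-in, since
    enhancer searches are usually restricted to exonic sequence.
    """
    exon = construct.segment(exon_label)
    if exon.sequence is None:
        raise ContextError(f"exon {exon_label!r} has no sequence to scan")
    if not include_flanking_introns:
        return pwm_scan(exon.sequence, pwms, c_anchor=exon.c_start)
    before = construct.intron_before(exon_label)
    after = construct.intron_after(exon_label)
    for seg in (before, after):
        if seg is not None and seg.sequence is None:
            raise ContextError(f"intron {seg.label!r} has no sequence")
    seq = ((before.sequence if before else "") + exon.sequence
           + (after.sequence if after else ""))
    anchor = exon.c_start - (before.length if before else 0)
    return pwm_scan(seq, pwms, c_anchor=anchor)


# ---------------------------------------------------------------------------
# intersecting hits with microdeletions
# ---------------------------------------------------------------------------

@dataclass
class OverlapRow:
    deletion: GenomicVariant
    removed_hits: list[MotifHit]      # fully or partially inside the deletion


@dataclass
class OverlapTable:
    rows: list[OverlapRow]

    def shared_hits(self) -> list[MotifHit]:
        """Hits removed by two or more deletions (e.g. a motif inside the
        overlap of two adjacent spliceogenic windows)."""
        counts: dict[MotifHit, int] = {}
        for row in self.rows:
            for h in row.removed_hits:
                counts[h] = counts.get(h, 0) + 1
        return [h for h, n in counts.items() if n >= 2]


def map_hits_to_deletions(hits: list[MotifHit],
                          deletions: list[GenomicVariant]) -> OverlapTable:
    """For each deletion, the motif hits it fully or partially removes.

    Coordinates must share the same c. frame (exonic integer positions).
    A hit overlapped by several deletions shows up in each of their rows;
    :meth:`OverlapTable.shared_hits` surfaces exactly those.
    """
    rows = []
    for d in deletions:
        a, b = d.span
        if a.offset or b.offset:
            raise ConfigurationError(
                f"{d.c_hgvs}: only exonic deletions map onto exonic hits")
        removed = [h for h in hits
                   if not (h.c_end < a.base or h.c_start > b.base)]
        rows.append(OverlapRow(deletion=d, removed_hits=removed))
    return OverlapTable(rows=rows)


def load_pwms(path) -> list[PWM]:
    """Load PWMs from YAML: a list of ``{name, threshold, matrix}`` where
    ``matrix`` is a list of ``{A,C,G,T}`` score columns."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [PWM(name=d["name"], matrix=[{b: float(col[b]) for b in _BASES}
                                        for col in d["matrix"]],
                threshold=float(d["threshold"]))
            for d in data["pwms"]]
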