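"""HGVS coding-DNA coordinate primitives.

Coding positions follow the HGVS c. convention: exonic positions are plain
1-based integers, intronic positions hang off the nearest exon boundary as
``c.7976+1`` (first intronic base after the donor) or ``c.7806-1`` (last
intronic base before the acceptor).  Internally a position is a
``(base, offset)`` pair; all interval arithmetic on the construct itself is
0-based half-open and conversion happens only at this boundary.

The grammar implemented here is deliberately small: substitutions,
deletions, duplications, insertions and delins over c. positions — the
variant classes a splicing-reporter assay actually tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

from .errors import CoordinateError

_POS_RE = re.compile(r"^(?P<base>\d+)(?P<off>[+-]\d+)?$")
_VARIANT_RE = re.compile(
    r"^c\.(?P<start>\d+(?:[+-]\d+)?)"
    r"(?:_(?P<end>\d+(?:[+-]\d+)?))?"
    r"(?P<rest>.*)$"
)


@total_ordering
@dataclass(frozen=True)
class CPos:
    """A coding-DNA position: exonic base plus optional intronic offset."""

    base: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise CoordinateError(f"c. base must be >= 1, got {self.base}")

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"

    def __lt__(self, other: "CPos") -> bool:
        return (self.base, self.offset) < (other.base, other.offset)

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0


def parse_cpos(text: str) -> CPos:
    """Parse ``"7806"``, ``"7806-1"`` or ``"7976+58"`` into a :class:`CPos`."""
    m = _POS_RE.match(text.strip())
    if not m:
        raise CoordinateError(f"unparseable c. position: {text!r}")
    off = m.group("off")
    return CPos(int(m.group("base")), int(off) if off else 0)


@dataclass
class CVariant:
    """A parsed HGVS c. description (one simple edit).

    ``span`` is the inclusive (start, end) interval the edit touches; for an
    insertion it is the flanking pair.  The positions are sorted, which also
    absorbs descriptions printed with the interval reversed (seen in the
    wild for intronic duplications such as ``c.7806-1_7806-2dup``).
    """

    c_hgvs: str
    edit_kind: str  # substitution | deletion | duplication | insertion | delins
    span: tuple[CPos, CPos]
    ref: str | None = None
    alt: str | None = None
    inserted_sequence: str | None = None


_SUB_RE = re.compile(r"^(?P<ref>[ACGT])>(?P<alt>[ACGT])$", re.I)
_DEL_RE = re.compile(r"^del(?:[ACGT]+|\d+)?$", re.I)
_DUP_RE = re.compile(r"^dup(?:[ACGT]+|\d+)?$", re.I)
_INS_RE = re.compile(r"^ins(?P<seq>[ACGT]+)$", re.I)
_DELINS_RE = re.compile(r"^delins(?P<seq>[ACGT]+)$", re.I)


def parse_c_hgvs(text: str) -> CVariant:
    """Parse a single HGVS c. variant string into a :class:`CVariant`."""
    s = text.strip()
    m = _VARIANT_RE.match(s)
    if not m:
        raise CoordinateError(f"unparseable HGVS c. description: {text!r}")
    start = parse_cpos(m.group("start"))
    end = parse_cpos(m.group("end")) if m.group("end") else start
    if end < start:
        start, end = end, start
    rest = m.group("rest")

    if (sub := _SUB_RE.match(rest)) is not None:
        if m.group("end"):
            raise CoordinateError(f"substitution over an interval: {text!r}")
        return CVariant(s, "substitution", (start, end),
                        ref=sub.group("ref").upper(), alt=sub.group("alt").upper())
    if (di := _DELINS_RE.match(rest)) is not None:
        return CVariant(s, "delins", (start, end),
                        inserted_sequence=di.group("seq").upper())
    if _DEL_RE.match(rest):
        return CVariant(s, "deletion", (start, end))
    if _DUP_RE.match(rest):
        return CVariant(s, "duplication", (start, end))
    if (ins := _INS_RE.match(rest)) is not None:
        return CVariant(s, "insertion", (start, end),
                        inserted_sequence=ins.group("seq").upper())
    raise CoordinateError(f"unsupported HGVS c. edit: {text!r}")


def format_interval(a: CPos, b: CPos) -> str:
    return str(a) if a == b else f"{a}_{b}"
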