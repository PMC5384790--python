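"""Fragment-analysis quantification.

Capillary-electrophoresis peak tables (size-called fragment size in nt,
height in RFU, area) are filtered at a detection floor, assigned to
candidate transcripts by size, and turned into per-transcript relative
abundances.  Two field conventions are baked in:

* peak **area**, not height, measures abundance — height only gates
  detection (default floor 50 RFU);
* with a single end-labelled fluorophore per amplicon the signal is
  proportional to molar amount, so no fragment-length correction is
  applied.

Peaks matching no candidate stay in the denominator as "unidentified"
aberrant mass — observed signal is never dropped.  Species absent from a
replicate count as zero in that replicate before averaging (flagged in
the result).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import AmbiguityError, QuantificationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_HEIGHT_RFU = 50.0
DEFAULT_TOLERANCE_NT = 0.4


@dataclass(frozen=True)
class Peak:
    """One called peak: size-called length, height and integrated area."""

    size_nt: float
    height_rfu: float
    area: float

    def __post_init__(self) -> None:
        if self.size_nt < 0 or self.height_rfu < 0 or self.area < 0:
            raise QuantificationError("peak fields must be nonnegative")


@dataclass
class PeakTable:
    """All peaks of one replicate run."""

    replicate_id: str
    peaks: list[Peak]
    metadata: dict = field(default_factory=dict)


@dataclass
class QuantResult:
    """Per-transcript fractions: replicate values, means and SDs.

    ``fractions`` holds per-replicate fractions (replicate -> label ->
    fraction, each replicate summing to 1); ``mean_sd`` the across-replicate
    arithmetic mean and sample SD per label (means again summing to 1).
    """

    fractions: dict[str, dict[str, float]]
    mean_sd: dict[str, tuple[float, float]]
    n_replicates: int
    flags: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.mean_sd)

    def mean(self, label: str) -> float:
        return self.mean_sd[label][0]

    @classmethod
    def from_fractions(cls, mean_fractions: dict[str, float],
                       n_replicates: int = 3,
                       flags: list[str] | None = None) -> "QuantResult":
        """Wrap already-averaged fractions (e.g. transcribed from a report)
        as a result with unknown dispersion."""
        total = sum(mean_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise QuantificationError(
                f"mean fractions sum to {total}, expected 1")
        return cls(fractions={}, n_replicates=n_replicates,
                   mean_sd={k: (v, float("nan")) for k, v in
                            mean_fractions.items()},
                   flags=(flags or []) + ["fractions supplied, not measured"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_peaks(table: PeakTable,
                 min_height_rfu: float = DEFAULT_MIN_HEIGHT_RFU) -> PeakTable:
    """Drop peaks strictly below the detection floor (kept when equal)."""
    kept = [p for p in table.peaks if p.height_rfu >= min_height_rfu]
    removed = len(table.peaks) - len(kept)
    if removed:
        logger.info("replicate %s: %d peak(s) below %.0f RFU removed",
                    table.replicate_id, removed, min_height_rfu)
    meta = dict(table.metadata, peaks_removed_below_floor=removed)
    return PeakTable(table.replicate_id, kept, meta)


def assign_peaks(table: PeakTable, candidates: dict[str, float],
                 tolerance_nt: float = DEFAULT_TOLERANCE_NT,
                 ) -> dict[str, Peak]:
    """Assign each peak to the nearest candidate size within tolerance.

    Candidate sizes must be pairwise distinct and the tolerance strictly
    below half the minimum candidate gap — otherwise one peak could match
    two candidates and the call is refused (:class:`AmbiguityError`), which
    forces the caller to tighten rather than silently mis-assign.  Peaks
    matching nothing land in ``unidentified-<size>`` buckets; two peaks on
    one candidate have their areas summed with a warning.
    """
    sizes = sorted(candidates.values())
    if len(set(sizes)) != len(sizes):
        raise AmbiguityError("candidate sizes are not pairwise distinct")
    if len(sizes) > 1:
        min_gap = min(b - a for a, b in zip(sizes, sizes[1:]))
        if tolerance_nt >= min_gap / 2:
            raise AmbiguityError(
                f"tolerance {tolerance_nt} nt >= half the minimum candidate "
                f"gap ({min_gap} nt): assignment would be ambiguous")
    out: dict[str, Peak] = {}
    for peak in table.peaks:
        label, best = None, None
        for cand, size in candidates.items():
            d = abs(peak.size_nt - size)
            if d <= tolerance_nt and (best is None or d < best):
                label, best = cand, d
        if label is None:
            label = f"unidentified-{peak.size_nt:.0f}"
        if label in out:
            prev = out[label]
            warnings.warn(
                f"replicate {table.replicate_id}: two peaks merged into "
                f"{label!r} (areas {prev.area:.0f} + {peak.area:.0f})")
            total = prev.area + peak.area
            out[label] = Peak(
                size_nt=(prev.size_nt * prev.area + peak.size_nt * peak.area)
                / total,
                height_rfu=max(prev.height_rfu, peak.height_rfu),
                area=total)
        else:
            out[label] = peak
    return out


def quantify(assigned: dict[str, dict[str, Peak]]) -> QuantResult:
    """Relative abundances from per-replicate assigned peaks.

    ``assigned`` maps replicate id -> (label -> peak).  Per replicate,
    ``fraction(label) = area(label) / total area``; labels absent from a
    replicate count as 0 there (flagged).  Across replicates the
    arithmetic mean and sample SD (ddof=1; 0 for a single replicate) are
    reported; fewer than three replicates warns, mirroring the
    at-least-in-triplicate convention of the assay.
    """
    if not assigned:
        raise QuantificationError("no replicates supplied")
    labels: list[str] = []
    for rep in assigned.values():
        for label in rep:
            if label not in labels:
                labels.append(label)
    if not labels:
        raise QuantificationError("no assigned peaks in any replicate")
    flags: list[str] = []
    fractions: dict[str, dict[str, float]] = {}
    for rep_id, peaks in assigned.items():
        total = sum(p.area for p in peaks.values())
        if total <= 0:
            raise QuantificationError(
                f"replicate {rep_id!r}: zero total peak area")
        fractions[rep_id] = {
            label: (peaks[label].area / total if label in peaks else 0.0)
            for label in labels}
        missing = [l for l in labels if l not in peaks]
        if missing:
            flags.append(f"replicate {rep_id}: absent labels counted as 0: "
                         + ", ".join(missing))
    n = len(fractions)
    if n < 3:
        warnings.warn(f"only {n} replicate(s); the assay convention is "
                      "at least three")
    df = pd.DataFrame(fractions).T  # replicates x labels
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1).fillna(0.0) if n > 1 else means * 0.0
    mean_sd = {label: (float(means[label]), float(sds[label]))
               for label in labels}
    return QuantResult(fractions=fractions, mean_sd=mean_sd,
                       n_replicates=n, flags=flags)


# ---------------------------------------------------------------------------
# TSV / JSON interfaces
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ["replicate_id", "size_nt", "height_rfu", "area"]


def read_peak_tables(path) -> list[PeakTable]:
    """Read the peak-table dialect: TSV (or CSV) with columns
    ``replicate_id, size_nt, height_rfu, area``; one table per replicate."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise QuantificationError(f"peak table missing columns: {missing}")
    tables = []
    for rep_id, grp in df.groupby("replicate_id", sort=False):
        peaks = [Peak(float(r.size_nt), float(r.height_rfu), float(r.area))
                 for r in grp.itertuples()]
        tables.append(PeakTable(str(rep_id), peaks))
    return tables


def write_peak_tables(tables: list[PeakTable], path) -> None:
    rows = [{"replicate_id": t.replicate_id, "size_nt": p.size_nt,
             "height_rfu": p.height_rfu, "area": p.area}
            for t in tables for p in t.peaks]
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def quant_result_frame(result: QuantResult, variant: str = "") -> pd.DataFrame:
    rows = [{"variant": variant, "label": label, "mean_fraction": m,
             "sd": s, "n": result.n_replicates}
            for label, (m, s) in result.mean_sd.items()]
    return pd.DataFrame(rows)


def write_quant_result(result: QuantResult, path, variant: str = "",
                       fmt: str = "tsv") -> None:
    if fmt == "tsv":
        quant_result_frame(result, variant).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {"variant": variant, "n_replicates": result.n_replicates,
                   "flags": result.flags,
                   "fractions": {label: {"mean": m, "sd": None if math.isnan(s)
                                         else s}
                                 for label, (m, s) in result.mean_sd.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
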