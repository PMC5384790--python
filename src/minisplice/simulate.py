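"""Synthetic data: reporter genes with valid splice sites and simulated
fragment-analyzer peak tables.

The generator exists so the whole pipeline is testable without any
download: it emits (a) multi-exon minigene constructs with GT/GC–AG splice
sites and a translatable CDS, and (b) per-replicate peak tables whose
per-transcript areas follow stated molar proportions under a simple noise
model — multiplicative lognormal area noise per peak per replicate, and
Gaussian size-calling jitter.  The defaults emulate the reproducibility of
a semi-quantitative fluorescent RT-PCR read on a capillary sequencer
(replicate SDs well under 2 percentage points); PCR amplification bias,
heteroduplexes and stutter are deliberately not modelled.

An optional per-transcript attenuation factor exists for completeness but
defaults to off, since the assays this emulates suppress NMD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .construct import MinigeneConstruct, PrimerSite, build_construct
from .consequence import CodingContext
from .errors import SpecError
from .quant import Peak, PeakTable
from .splice import CandidateTable, candidate_transcript_table

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in _STOPS]


@dataclass
class SimulationParams:
    """Noise model and scale for simulated electropherogram peak tables.

    ``area_cv`` is the lognormal coefficient of variation of each peak's
    area; the default 0.04 is calibrated so that replicate SDs of the
    recovered fractions stay below 1.8 percentage points even for the
    worst-case 50/50 mixture (SD of a fraction scales roughly as
    cv * f * (1-f) * sqrt(2)), matching the reproducibility regime of the
    assay this emulates;
    ``size_jitter_sd_nt`` the SD of the size-calling error (default 0.1 nt,
    sub-nucleotide as on a capillary with a dense size standard);
    ``peak_sigma_nt`` the Gaussian peak width used to derive heights from
    areas; ``rfu_scale`` the total signal per replicate.
    """

    true_fractions: dict[str, float]
    peak_sigma_nt: float = 0.5
    area_cv: float = 0.04
    size_jitter_sd_nt: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    rfu_scale: float = 100_000.0
    attenuation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.true_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SpecError(f"true fractions sum to {total}, expected 1")
        if min(self.true_fractions.values(), default=0.0) < 0:
            raise SpecError("fractions must be nonnegative")
        if self.peak_sigma_nt < 0 or self.area_cv < 0 \
                or self.size_jitter_sd_nt < 0:
            raise SpecError("dispersions must be >= 0")
        if self.n_replicates < 1:
            raise SpecError("need at least one replicate")


@dataclass
class SyntheticGeneSpec:
    """Shape of a synthetic multi-exon reporter gene.

    ``donor_styles`` optionally fixes the +1/+2 dinucleotide of each
    intron's donor (``GT`` or ``GC``); default all-GT.  Exons must be at
    least 6 nt (so the protected 2+3 terminal nucleotides exist), introns
    at least 20 nt.
    """

    n_exons: int = 3
    exon_length_range: tuple[int, int] = (60, 150)
    intron_length_range: tuple[int, int] = (60, 200)
    donor_styles: list[str] | None = None
    vector_exon_lengths: tuple[int, int] = (200, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise SpecError("need at least one exon")
        if self.exon_length_range[0] < 6:
            raise SpecError("exons must be >= 6 nt (protected ends)")
        if self.intron_length_range[0] < 20:
            raise SpecError("introns must be >= 20 nt")
        if self.donor_styles is not None:
            if len(self.donor_styles) != self.n_exons + 1:
                raise SpecError("one donor style per intron "
                                f"({self.n_exons + 1} introns)")
            if any(s not in ("GT", "GC") for s in self.donor_styles):
                raise SpecError("donor styles must be GT or GC")


@dataclass
class SyntheticMinigene:
    """A generated construct plus the coding context matching its exons."""

    construct: MinigeneConstruct
    coding_context: CodingContext


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_synthetic_minigene(spec: SyntheticGeneSpec) -> SyntheticMinigene:
    """Generate a reporter construct with sequences and a translatable CDS.

    The concatenated exons form the CDS: ATG first, a stop codon last, no
    internal stop in frame (codons drawn from the 61 sense codons).  Each
    intron starts with its donor dinucleotide (GT, or GC where requested)
    and ends with an AG acceptor.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo_e, hi_e = spec.exon_length_range
    exon_lengths = [int(rng.integers(lo_e, hi_e + 1))
                    for _ in range(spec.n_exons)]
    total = sum(exon_lengths)
    exon_lengths[-1] += (-total) % 3           # CDS length divisible by 3
    total = sum(exon_lengths)
    n_codons = total // 3
    if n_codons < 3:
        raise SpecError("CDS too short for start + body + stop")
    codons = ["ATG"] + [
        _NONSTOP_CODONS[int(rng.integers(0, len(_NONSTOP_CODONS)))]
        for _ in range(n_codons - 2)] + ["TAA"]
    cds = "".join(codons)

    lo_i, hi_i = spec.intron_length_range
    styles = spec.donor_styles or ["GT"] * (spec.n_exons + 1)

    def intron_seq(style: str, n: int) -> str:
        return style + _random_seq(rng, n - 4) + "AG"

    segments: list[dict] = [
        {"role": "vector_exon", "label": "V1",
         "length": spec.vector_exon_lengths[0],
         "sequence": _random_seq(rng, spec.vector_exon_lengths[0])}]
    pos = 0
    for i, elen in enumerate(exon_lengths):
        ilen = int(rng.integers(lo_i, hi_i + 1))
        segments.append({"role": "intron", "label": f"IVS{i}",
                         "length": ilen,
                         "sequence": intron_seq(styles[i], ilen)})
        segments.append({"role": "exon", "label": f"EX{i + 1}",
                         "length": elen, "c_start": pos + 1,
                         "c_end": pos + elen,
                         "sequence": cds[pos:pos + elen]})
        pos += elen
    ilen = int(rng.integers(lo_i, hi_i + 1))
    segments.append({"role": "intron", "label": f"IVS{spec.n_exons}",
                     "length": ilen,
                     "sequence": intron_seq(styles[-1], ilen)})
    segments.append({"role": "vector_exon", "label": "V2",
                     "length": spec.vector_exon_lengths[1],
                     "sequence": _random_seq(rng, spec.vector_exon_lengths[1])})
    primers = [
        {"name": "V1-FW", "segment": "V1",
         "offset_from_segment_end": min(20, spec.vector_exon_lengths[0]),
         "direction": "forward"},
        {"name": "V2-RV", "segment": "V2",
         "offset_from_segment_end": min(20, spec.vector_exon_lengths[1]),
         "direction": "reverse"}]
    construct = build_construct({"name": f"synthetic-{spec.seed}",
                                 "segments": segments, "primers": primers})
    # a native 3' UTR continuation so frameshifted readings terminate
    utr = _random_seq(rng, 99)
    return SyntheticMinigene(construct=construct,
                             coding_context=CodingContext(
                                 cds, downstream_sequence=utr))


# ---------------------------------------------------------------------------
# peak-table simulation
# ---------------------------------------------------------------------------

def simulate_peak_table(candidates: dict[str, float],
                        params: SimulationParams) -> list[PeakTable]:
    """Simulate per-replicate size-called peak tables for a known mixture.

    Per replicate, each nonzero-fraction species gets one peak:
    ``area = rfu_scale * fraction * LogNormal(cv)`` (unit mean), size =
    candidate size + Gaussian jitter, and height derived from area and the
    Gaussian peak width.  Values are rounded to fixed precision (size 2 dp,
    area/height 3 dp) so recorded tables are deterministic across
    platforms for a given seed.
    """
    if not candidates:
        raise SpecError("no candidate sizes supplied")
    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(math.log(1.0 + params.area_cv ** 2))
    tables: list[PeakTable] = []
    for r in range(params.n_replicates):
        peaks: list[Peak] = []
        for label, frac in params.true_fractions.items():
            if frac <= 0:
                continue
            if label not in candidates:
                raise SpecError(f"no candidate size for species {label!r}")
            noise = (rng.lognormal(-sigma ** 2 / 2.0, sigma)
                     if sigma > 0 else 1.0)
            att = params.attenuation.get(label, 1.0)
            area = params.rfu_scale * frac * noise * att
            size = candidates[label] + (
                rng.normal(0.0, params.size_jitter_sd_nt)
                if params.size_jitter_sd_nt > 0 else 0.0)
            height = area / (params.peak_sigma_nt * math.sqrt(2 * math.pi))
            peaks.append(Peak(size_nt=round(size, 2),
                              height_rfu=round(height, 3),
                              area=round(area, 3)))
        tables.append(PeakTable(replicate_id=f"rep{r + 1}", peaks=peaks,
                                metadata={"seed": params.seed,
                                          "replicate_index": r}))
    return tables


@dataclass
class AssayBundle:
    """Everything one simulated variant assay feeds the pipeline."""

    variant: str
    candidates: CandidateTable
    peak_tables: list[PeakTable]
    true_fractions: dict[str, float]


def simulate_assay(construct: MinigeneConstruct,
                   truth: dict[str, tuple[dict, dict[str, float]]],
                   params: SimulationParams,
                   fwd: PrimerSite, rev: PrimerSite) -> dict[str, AssayBundle]:
    """End-to-end simulation: variant -> (event catalog, true fractions).

    For each variant, builds the candidate-size table via the splice
    engine and simulates replicate peak tables at the stated proportions.
    Seeds for each variant are derived deterministically from
    ``params.seed`` so bundles are independent but reproducible.
    """
    bundles: dict[str, AssayBundle] = {}
    for i, (variant, (catalog, fractions)) in enumerate(sorted(truth.items())):
        table = candidate_transcript_table(construct, catalog, fwd, rev)
        p = SimulationParams(
            true_fractions=fractions, peak_sigma_nt=params.peak_sigma_nt,
            area_cv=params.area_cv,
            size_jitter_sd_nt=params.size_jitter_sd_nt,
            n_replicates=params.n_replicates,
            seed=(params.seed * 1_000 + i) % (2 ** 31),
            rfu_scale=params.rfu_scale, attenuation=params.attenuation)
        bundles[variant] = AssayBundle(
            variant=variant, candidates=table,
            peak_tables=simulate_peak_table(table.sizes, p),
            true_fractions=fractions)
    return bundles


# ---------------------------------------------------------------------------
# raw-trace rendering and a simple caller (simulated traces only)
# ---------------------------------------------------------------------------

def render_trace(peaks: list[Peak], grid: np.ndarray,
                 sigma_nt: float = 0.5) -> np.ndarray:
    """Render called peaks as a Gaussian-mixture fluorescence trace."""
    y = np.zeros_like(grid, dtype=float)
    for p in peaks:
        y += (p.area / (sigma_nt * math.sqrt(2 * math.pi))
              * np.exp(-0.5 * ((grid - p.size_nt) / sigma_nt) ** 2))
    return y


def call_peaks(grid: np.ndarray, trace: np.ndarray,
               min_height_rfu: float = 50.0,
               sigma_nt: float = 0.5) -> list[Peak]:
    """Call peaks on a simulated trace (local maxima above the floor).

    This is a convenience for round-tripping simulated traces, not a
    general electropherogram caller: no baseline correction or size
    calibration is attempted.
    """
    idx, props = find_peaks(trace, height=min_height_rfu)
    out = []
    for i in idx:
        height = float(trace[i])
        out.append(Peak(size_nt=float(grid[i]), height_rfu=height,
                        area=height * sigma_nt * math.sqrt(2 * math.pi)))
    return out
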