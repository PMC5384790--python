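"""Splicing-viewpoint variant interpretation.

A variant is *spliceogenic* when at least 5% of its transcript mass is
anomalous (everything that is not the canonical full-length transcript,
including unidentified species).  Spliceogenic variants are then run
through a small codified decision table:

* **R1** — the variant alters a canonical ±1/±2 splice-site dinucleotide
  and ≥95% of the transcript mass is aberrant → *pathogenic*;
* **R2** — the variant is a predicted truncating change at the DNA level
  (nonsense or frameshift) and ≥95% aberrant → *pathogenic*;
* **R3** — otherwise ≥55% aberrant → *likely pathogenic* (the 0.55 cut sits
  just under the ~60% level discussed in the clinical splicing literature
  as marking severe splicing aberration);
* **R4** — otherwise (≥5%) → *uncertain significance*; independent prior
  evidence (e.g. an established protein-level classification) may upgrade
  the **final** label, and is always recorded as a triggered rule;
* **R5** — below 5% → *not spliceogenic*.

``Classification.label`` is the splicing-viewpoint outcome of the table
alone; ``final_label`` additionally applies any prior-evidence upgrade.
Keeping the two apart mirrors how assay cohorts are reported: variants
already classified on protein grounds are not counted in the
splicing-based pathogenic/likely-pathogenic lists, yet no longer sit in
the uncertain class either.  All thresholds are configuration, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .consequence import Consequence
from .construct import GenomicVariant
from .errors import AnnotationError, ConfigurationError
from .quant import QuantResult

CANONICAL_LABEL = "FL"

_LABEL_ORDER = ["not_spliceogenic", "vus", "likely_pathogenic", "pathogenic"]


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision-table cutpoints on the aberrant transcript fraction."""

    spliceogenic: float = 0.05
    likely_pathogenic: float = 0.55
    pathogenic: float = 0.95


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass(frozen=True)
class PriorEvidence:
    """An independent, non-splicing prior classification for a variant."""

    label: str          # e.g. "likely_pathogenic"
    reason: str         # e.g. "protein function"


@dataclass
class VariantAssay:
    """One variant's assembled assay: identity, quantification, annotation."""

    variant: GenomicVariant
    quant: QuantResult
    transcript_consequences: dict[str, Consequence | None] = \
        field(default_factory=dict)
    prior_evidence: PriorEvidence | None = None
    region: str | None = None        # e.g. "ex17" / "ex18"

    def __post_init__(self) -> None:
        for label in self.quant.labels:
            if label == CANONICAL_LABEL:
                continue
            if label not in self.transcript_consequences:
                # placeholders are flagged, never silently invented
                self.transcript_consequences[label] = None


@dataclass
class Classification:
    """Decision-table outcome for one variant."""

    label: str                       # splicing-viewpoint label
    final_label: str                 # after prior-evidence integration
    aberrant_fraction: float
    triggered_rules: list[str]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def aberrant_fraction(assay: VariantAssay) -> float:
    """1 − mean canonical-transcript fraction; unidentified mass is aberrant.

    The canonical label must be part of the quantified catalog (possibly at
    fraction 0); otherwise the assay bundle is misconfigured.
    """
    if CANONICAL_LABEL not in assay.quant.mean_sd:
        raise ConfigurationError(
            f"{assay.variant.c_hgvs}: no canonical ({CANONICAL_LABEL}) "
            "candidate in the quantified catalog")
    return 1.0 - assay.quant.mean(CANONICAL_LABEL)


def is_spliceogenic(assay: VariantAssay,
                    threshold: float = DEFAULT_THRESHOLDS.spliceogenic) -> bool:
    """At or above the anomalous-mass threshold (inclusive at the boundary)."""
    return aberrant_fraction(assay) >= threshold


def classify_variant(assay: VariantAssay,
                     thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
                     ) -> Classification:
    """Run the splicing-viewpoint decision table on one assembled assay."""
    v = assay.variant
    if v.site_class is None:
        raise AnnotationError(f"{v.c_hgvs}: site_class not populated")
    if v.direct_coding_prediction is None:
        raise AnnotationError(
            f"{v.c_hgvs}: direct_coding_prediction not populated")
    ab = aberrant_fraction(assay)
    rules: list[str] = []

    if ab < thresholds.spliceogenic:
        rules.append(f"R5: aberrant {ab:.3f} < {thresholds.spliceogenic:g}"
                     " -> not spliceogenic")
        label = "not_spliceogenic"
    elif (v.site_class == "canonical_dinucleotide"
          and ab >= thresholds.pathogenic):
        rules.append(f"R1: canonical +/-1,2 site and aberrant {ab:.3f} >= "
                     f"{thresholds.pathogenic:g} -> pathogenic")
        label = "pathogenic"
    elif (v.direct_coding_prediction in ("nonsense", "frameshift")
          and ab >= thresholds.pathogenic):
        rules.append(f"R2: predicted {v.direct_coding_prediction} and "
                     f"aberrant {ab:.3f} >= {thresholds.pathogenic:g}"
                     " -> pathogenic")
        label = "pathogenic"
    elif ab >= thresholds.likely_pathogenic:
        rules.append(f"R3: aberrant {ab:.3f} >= "
                     f"{thresholds.likely_pathogenic:g} -> likely pathogenic")
        label = "likely_pathogenic"
    else:
        rules.append(f"R4: aberrant {ab:.3f} >= {thresholds.spliceogenic:g}"
                     " -> uncertain significance")
        label = "vus"

    final = label
    if assay.prior_evidence is not None and label == "vus":
        prior = assay.prior_evidence
        if _LABEL_ORDER.index(prior.label) > _LABEL_ORDER.index(label):
            final = prior.label
            rules.append(f"PRIOR: upgraded vus -> {prior.label} "
                         f"({prior.reason})")
    return Classification(label=label, final_label=final,
                          aberrant_fraction=ab, triggered_rules=rules)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    n_variants: int = 0
    n_spliceogenic: int = 0
    n_with_full_exon_skip: int = 0
    aberrant_species: set = field(default_factory=set)


@dataclass
class CohortSummary:
    """Cohort-level counts of a classified assay collection.

    Class counts are splicing-viewpoint counts; variants whose final label
    was upgraded by prior evidence are counted separately
    (``n_prior_upgraded``) and in ``n_vus_final`` they are excluded.
    """

    n_variants: int
    n_spliceogenic: int
    n_pathogenic: int
    n_likely_pathogenic: int
    n_vus: int
    n_vus_final: int
    n_not_spliceogenic: int
    n_prior_upgraded: int
    per_region: dict[str, RegionSummary]
    classifications: dict[str, Classification]

    @property
    def fraction_spliceogenic(self) -> float:
        return self.n_spliceogenic / self.n_variants if self.n_variants else 0.0


def _is_characterized(assay: VariantAssay, label: str) -> bool:
    return (label != CANONICAL_LABEL
            and assay.transcript_consequences.get(label) is not None)


def cohort_summary(assays: list[VariantAssay],
                   thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
                   ) -> CohortSummary:
    """Classify every assay and aggregate the cohort.

    Per exon region the summary counts variants, spliceogenic variants,
    variants whose outcome includes *full* skipping of that region's exon
    (label ``"<region> skipping"``, alone or inside a composite), and the
    set of distinct structurally characterised aberrant species.
    """
    classifications: dict[str, Classification] = {}
    per_region: dict[str, RegionSummary] = {}
    n_spliceo = n_p = n_lp = n_vus = n_vus_final = n_not = n_prior = 0
    for assay in assays:
        c = classify_variant(assay, thresholds)
        classifications[assay.variant.c_hgvs] = c
        spliceo = c.label != "not_spliceogenic"
        n_spliceo += spliceo
        n_p += c.label == "pathogenic"
        n_lp += c.label == "likely_pathogenic"
        n_vus += c.label == "vus"
        n_vus_final += c.final_label == "vus"
        n_not += c.label == "not_spliceogenic"
        n_prior += c.final_label != c.label

        region = assay.region or "unassigned"
        rs = per_region.setdefault(region, RegionSummary())
        rs.n_variants += 1
        if spliceo:
            rs.n_spliceogenic += 1
            skip_label = f"{region} skipping"
            present = [l for l in assay.quant.labels
                       if assay.quant.mean(l) > 0]
            if any(l == skip_label or l.endswith("+" + skip_label)
                   or l.startswith(skip_label + "+") for l in present):
                rs.n_with_full_exon_skip += 1
            for l in present:
                if _is_characterized(assay, l):
                    rs.aberrant_species.add(l)
    return CohortSummary(
        n_variants=len(assays), n_spliceogenic=n_spliceo,
        n_pathogenic=n_p, n_likely_pathogenic=n_lp, n_vus=n_vus,
        n_vus_final=n_vus_final, n_not_spliceogenic=n_not,
        n_prior_upgraded=n_prior, per_region=per_region,
        classifications=classifications)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report_frame(assays: list[VariantAssay],
                 thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
                 ) -> pd.DataFrame:
    """Assay-cohort report: one row per variant, outcome-table style."""
    rows = []
    for assay in assays:
        c = classify_variant(assay, thresholds)
        outcomes = "; ".join(
            f"{label} ({100 * assay.quant.mean(label):.1f}%)"
            for label in assay.quant.labels
            if assay.quant.mean(label) > 0)
        rows.append({
            "variant": assay.variant.c_hgvs,
            "region": assay.region,
            "site_class": assay.variant.site_class,
            "coding_prediction": assay.variant.direct_coding_prediction,
            "outcomes": outcomes,
            "aberrant_fraction": round(c.aberrant_fraction, 4),
            "classification": c.label,
            "final_classification": c.final_label,
            "rules": " | ".join(c.triggered_rules),
        })
    return pd.DataFrame(rows)


def write_report(assays: list[VariantAssay], path, fmt: str = "tsv",
                 thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
                 ) -> None:
    df = report_frame(assays, thresholds)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
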