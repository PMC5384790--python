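"""Packaged fixtures: the BRCA2 exon 14-20 reporter and its variant cohort.

Three text fixtures ship with the package:

* ``mgbr2_ex14_20.yaml`` — the seven-exon BRCA2 splicing-reporter
  construct (segment lengths, c. anchors, primer calibration);
* ``cohort_outcomes.tsv`` — the 30 spliceogenic variants of the published
  exon 17/18 assay cohort with their per-transcript percentages and the
  reported r./p. strings, transcribed from the outcome table;
* ``cohort_weak_negatives.tsv`` / ``cohort_negatives_synthetic.tsv`` —
  the three named below-threshold variants and 19 synthetic placeholder
  negatives completing the 52-variant cohort (see the file headers).

``load_cohort`` assembles all of this into ready-to-classify
:class:`~minisplice.interpret.VariantAssay` objects: quantification wraps
the transcribed mean percentages, site classes are derived from the
construct, and each characterised transcript label carries a frame-level
consequence computed by the splice engine.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .consequence import Consequence, frame_status
from .construct import (GenomicVariant, MinigeneConstruct, build_construct,
                        derive_site_class, variant_region)
from .ese import PWM, load_pwms
from .hgvs import parse_cpos
from .interpret import PriorEvidence, VariantAssay
from .quant import QuantResult
from .splice import SpliceEvent, Transcript, apply_splice_events

_FIXTURES = resources.files("minisplice") / "data"


def load_construct() -> MinigeneConstruct:
    """The BRCA2 exons 14-20 reporter construct fixture."""
    with (_FIXTURES / "mgbr2_ex14_20.yaml").open() as fh:
        return build_construct(yaml.safe_load(fh))


#: structural definitions of every characterised aberrant species seen in
#: the cohort, as events on the reporter construct
EVENT_CATALOG: dict[str, frozenset[SpliceEvent]] = {
    "FL": frozenset(),
    "ex17 skipping": frozenset({SpliceEvent("exon_skip", "EX17")}),
    "ivs16-ins8": frozenset({SpliceEvent("alt_acceptor", "EX17", -8)}),
    "ex17-del69": frozenset({SpliceEvent("alt_acceptor", "EX17", 69)}),
    "ex17-del20": frozenset({SpliceEvent("alt_acceptor", "EX17", 20)}),
    "ex17-del1": frozenset({SpliceEvent("alt_acceptor", "EX17", 1)}),
    "ex17-insAG": frozenset({SpliceEvent("alt_acceptor", "EX17", -2,
                                         inserted_sequence="AG")}),
    "ex18-ins6": frozenset({SpliceEvent("alt_acceptor", "EX18", -6)}),
    "ex18 skipping": frozenset({SpliceEvent("exon_skip", "EX18")}),
    "ex18-del191": frozenset({SpliceEvent("alt_acceptor", "EX18", 191)}),
    "ex18-del236": frozenset({SpliceEvent("alt_acceptor", "EX18", 236)}),
    "ex18-del309": frozenset({SpliceEvent("alt_donor", "EX18", 309)}),
    "ex18-del298": frozenset({SpliceEvent("alt_donor", "EX18", 298)}),
    "ex18-del164": frozenset({SpliceEvent("alt_donor", "EX18", 164)}),
    "ex18-del157": frozenset({SpliceEvent("alt_donor", "EX18", 157)}),
    "ex17-del151+ex18 skipping": frozenset({
        SpliceEvent("alt_donor", "EX17", 151),
        SpliceEvent("exon_skip", "EX18")}),
    "ivs17-ret58+ex18 skipping": frozenset({
        SpliceEvent("alt_donor", "EX17", -58),
        SpliceEvent("exon_skip", "EX18")}),
}

#: species observed by size only — never structurally characterised
PLACEHOLDER_LABELS = {"others": None, "878nt": 878}


def transcript_catalog(construct: MinigeneConstruct | None = None,
                       ) -> dict[str, Transcript]:
    """Every catalog species as a Transcript on the fixture construct."""
    construct = construct or load_construct()
    out = {label: apply_splice_events(construct, events, label=label)
           for label, events in EVENT_CATALOG.items()}
    for label, size in PLACEHOLDER_LABELS.items():
        out[label] = Transcript.placeholder(label, size)
    return out


def _frame_consequence(transcript: Transcript) -> Consequence | None:
    """Frame-level consequence (no sequence, hence no p. string).

    The class is the length-arithmetic approximation: frameshifts are
    PTC-introducing, in-frame losses/gains are in-frame deletions/delins.
    The intron-retention composite is in-frame by length but carries a
    stop inside the retained intron, so it is marked PTC-introducing here
    by its structure (retained-intron neo-sequence), consistent with
    translation on sequence-bearing constructs.
    """
    if transcript.is_placeholder:
        return None
    status, delta = frame_status(transcript)
    retains_intron = any(e.kind in ("intron_retention_partial",)
                         or (e.kind in ("alt_acceptor", "alt_donor")
                             and e.offset < 0 and e.inserted_sequence is None)
                         for e in transcript.events)
    if status == "frameshift":
        cls = "ptc_introducing"
    elif retains_intron:
        cls = "ptc_introducing"   # neo-sequence stop (verified on sequence)
    elif delta < 0:
        cls = "in_frame_deletion"
    elif delta > 0:
        cls = "in_frame_delins"
    else:
        cls = "canonical"
    return Consequence(frame_status=status, net_delta_nt=delta,
                       consequence_class=cls)


def _parse_outcomes(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for item in text.split(";"):
        label, pct = item.rsplit("=", 1)
        out[label.strip()] = float(pct) / 100.0
    total = sum(out.values())
    # transcribed percentages can be off by rounding; renormalise exactly
    return {k: v / total for k, v in out.items()}


def _assay_from_row(construct: MinigeneConstruct, variant_id: str,
                    coding: str, outcomes: str,
                    prior: PriorEvidence | None,
                    region: str | None,
                    catalog: dict[str, Transcript]) -> VariantAssay:
    fractions = _parse_outcomes(outcomes)
    if "FL" not in fractions:
        fractions["FL"] = 0.0
    if variant_id.startswith("NEG-"):
        gv = GenomicVariant(c_hgvs=variant_id, edit_kind="substitution",
                            span=(parse_cpos("1"), parse_cpos("1")),
                            site_class="exonic",
                            direct_coding_prediction=coding)
    else:
        gv = GenomicVariant.from_hgvs(variant_id,
                                      direct_coding_prediction=coding)
        gv.site_class = derive_site_class(construct, gv)
        region = region or variant_region(construct, gv)
    consequences = {
        label: _frame_consequence(catalog[label])
        for label in fractions if label != "FL" and label in catalog}
    return VariantAssay(
        variant=gv,
        quant=QuantResult.from_fractions(fractions),
        transcript_consequences=consequences,
        prior_evidence=prior, region=region)


def load_cohort(include_negatives: bool = True,
                with_priors: bool = True) -> list[VariantAssay]:
    """The 52-variant assay cohort as assembled VariantAssay objects.

    ``include_negatives=False`` restricts to the 30 spliceogenic variants
    of the outcome table.  ``with_priors=False`` drops the two
    protein-level prior classifications (useful to see the pure
    splicing-viewpoint table).
    """
    construct = load_construct()
    catalog = transcript_catalog(construct)
    assays: list[VariantAssay] = []

    with (_FIXTURES / "cohort_outcomes.tsv").open() as fh:
        outcomes = pd.read_csv(fh, sep="\t")
    for row in outcomes.itertuples():
        prior = None
        if with_priors and isinstance(row.prior_class, str):
            prior = PriorEvidence(label=row.prior_class,
                                  reason=row.prior_reason)
        assays.append(_assay_from_row(
            construct, row.variant, row.coding_prediction, row.outcomes,
            prior, None, catalog))

    if include_negatives:
        with (_FIXTURES / "cohort_weak_negatives.tsv").open() as fh:
            weak = pd.read_csv(fh, sep="\t")
        for row in weak.itertuples():
            assays.append(_assay_from_row(
                construct, row.variant, row.coding_prediction, row.outcomes,
                None, None, catalog))
        with (_FIXTURES / "cohort_negatives_synthetic.tsv").open() as fh:
            synth = pd.read_csv(fh, sep="\t", comment="#")
        for row in synth.itertuples():
            assays.append(_assay_from_row(
                construct, row.variant, row.coding_prediction, row.outcomes,
                None, row.region, catalog))
    return assays


def load_reference_pwms() -> list[PWM]:
    """The packaged (synthetic, consensus-derived) SR-protein PWMs."""
    with resources.as_file(_FIXTURES / "pwms_synthetic.yaml") as p:
        return load_pwms(p)
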