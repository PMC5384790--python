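# Methods

This note records the models, conventions and numerical choices behind
minisplice, and what the synthetic-data tests do and do not establish.

## Construct model and coordinates

A reporter construct is an ordered list of segments: a 5' vector exon,
alternating cloned introns and exons, a 3' vector exon. Cloned exons carry
HGVS c. anchors (1-based inclusive); intronic positions are written
relative to the flanking exon boundaries (`c.7976+1`, `c.7806-1`).
Internally every position maps to `(segment, offset)` with 0-based
half-open spans; conversion happens only at the HGVS boundary, which keeps
interval arithmetic unambiguous. The construct is modelled in transcript
orientation only — a minigene is a single-orientation insert, so no
reverse-strand genomics exists anywhere in the package.

Construct maps often print shortened introns as two pieces around a gap;
`build_construct` accepts them that way and merges adjacent intron pieces
so the validated construct satisfies strict exon/intron alternation.

Sequences are optional everywhere. All size and frame arithmetic is
length-only; operations that genuinely need nucleotides (translation,
realising a retained intron fragment, sequence editing) raise a
`ContextError` rather than inventing sequence.

### Primer calibration

Primer tail lengths inside the reporter vector are not observable from an
assay readout; only the *sum* of the forward and reverse tails enters any
amplicon size. The packaged construct therefore fixes the tails by
calibration: the vector-exon pair is set to give the known 1,806-nt
full-length product over the 1,625 nt of cloned exons (tail sum 181,
split 131/50), and the exon-16 pair to give its known 1,012-nt product
(tail sum 185, split 135/50). The splits are arbitrary and documented in
the fixture; no result depends on them individually.

### Microdeletion design

Enhancer mapping deletes exonic windows while preserving the first two
and last three nucleotides of the exon (they belong to the acceptor/donor
definitions). The designer tiles windows across the exon interior or
across requested intervals; overlapping windows arise naturally from
overlapping requests. Any request reaching the protected ends is refused.

## Splice events and transcript descriptions

Events are structural offsets from annotated exon boundaries — skip,
alternative acceptor/donor shifted into the exon (deletion) or into the
intron (insertion), partial intron retention. Whether a site is "cryptic"
or "de novo" is mechanism metadata the engine does not need. At most one
acceptor-side and one donor-side alteration per exon may compose; events
are a set, so composition is order-independent by construction.

HGVS r. strings are generated in spliced-mRNA space: exonic deletions
adjacent across an exon junction merge into one contiguous `del` (the
composite "lose the 3' end of exon 17 and skip exon 18" becomes
`r.7826_8331del`); an intronic extension flanking a deletion becomes
`delins`; disjoint alterations join as `r.[a;b]`. A deliberate limitation:
intronic extensions at the construct's terminal exons have no describable
junction and raise an unsupported-description error rather than emitting
an ill-formed string. Uncharacterised species ("others", a lone 878-nt
product) are size-only placeholders — quantification keeps their mass,
and every structural operation rejects them loudly.

## Protein consequences

Frame status is pure arithmetic: net Δnt mod 3. Everything else comes
from translating the mutant coding sequence against the reference CDS.
The PTC rule distinguishes two regimes:

* **Frameshift** (Δ mod 3 ≠ 0): the reading downstream of the first
  altered residue is novel; the first stop anywhere in it is a PTC
  (`p.X123Yfs*N`, N counting from the first altered residue to the stop
  inclusive).
* **In-frame** (Δ mod 3 = 0): downstream of the altered interval the
  reference sequence continues in its reference frame, so the reference
  stop always survives at residue index `len(reference) + Δ/3`. A stop
  strictly earlier than that index is a PTC (neo-sequence stop, e.g. in a
  retained intron); a stop exactly there means the protein rejoined the
  reference and the change is an in-frame deletion/insertion/delins.

This rule is exact, needs no heuristics about "changed regions", and is
what the brute-force oracle in the test suite verifies over ≥1,000 random
synthetic construct/event cases. Changed regions are 3'-normalised
(maximal common prefix, then suffix) before p. strings are written,
matching HGVS practice. Two honest edge classes extend the vocabulary:
`frameshift_no_stop` (the shifted reading runs off the modelled sequence —
the context should then be extended with the native 3' continuation,
which `CodingContext.downstream_sequence` holds) and `no_stop` (an
in-frame event removed the reference stop).

No NMD rules (50-nt boundary etc.) are applied anywhere: the assay class
this package interprets suppresses nonsense-mediated decay
pharmacologically, so aberrant transcripts are quantified at their true
abundance and degradation is out of model. An optional per-transcript
attenuation factor exists in the simulator for completeness and defaults
to off.

## Quantification

Peak area is the abundance measure; height is used only for the detection
floor (default ≥50 RFU, inclusive). With a single end-labelled fluorophore
per amplicon the fluorescent signal is proportional to the molar amount of
product, so no fragment-length correction is applied. Per replicate,
`fraction(label) = area / Σ areas`; across replicates, arithmetic mean and
sample SD (ddof = 1). Fewer than three replicates triggers a warning, not
an error, mirroring the at-least-in-triplicate assay convention.

Size assignment is nearest-candidate within a tolerance (default 0.4 nt).
The tolerance must be strictly below half the minimum candidate gap —
candidates in this assay class can sit 1 nt apart — otherwise the call is
refused with an ambiguity error; silent mis-assignment is the failure mode
this guards against. Peaks matching no candidate become
`unidentified-<size>` buckets and remain in the denominator as aberrant
mass. A species absent from some replicates counts as zero there before
averaging (the alternative — renormalising over present species — would
bias fractions upward); the result flags every such case.

## Synthetic data

The generator emits (a) multi-exon reporter genes whose concatenated
exons form a translatable CDS (ATG start, stop at the end, the 61 sense
codons in between) with GT- or GC-donor/AG-acceptor introns, and (b)
size-called peak tables under a two-parameter noise model: multiplicative
lognormal area noise per peak per replicate, and Gaussian size-calling
jitter.

Defaults (the simulated study conditions): 3 replicates, area CV 0.04,
size jitter SD 0.1 nt, peak width 0.5 nt, total signal 10⁵ RFU·nt. The
area CV is calibrated to the reproducibility regime of the emulated
readout — replicate SDs of recovered fractions below 1.8 percentage
points: the SD of a two-species fraction scales as ≈ cv·f(1−f)·√2, so CV
0.04 keeps even the worst-case 50/50 mixture at ~1.7 points. Size jitter
of 0.1 nt makes mis-assignment of 1-nt-apart candidates at the 0.4-nt
tolerance a ≈4σ event. Values are recorded at fixed precision (size 2 dp,
area/height 3 dp) so tables are byte-stable across platforms for a seed.

What the simulator does *not* emulate: PCR amplification bias,
heteroduplex and stutter artefacts, baseline drift, or size-standard
calibration error. Passing recovery tests therefore show that the
quantification chain is correct and well-conditioned under calibrated
noise — not that real electropherograms are this clean. The bundled
Gaussian peak caller is for round-tripping simulated traces only.

## Classification

Spliceogenicity: aberrant fraction = 1 − mean full-length fraction
(unidentified mass counts as aberrant), threshold 0.05, inclusive at the
boundary. The decision table, all thresholds configuration:

| rule | condition | label |
|------|-----------|-------|
| R1 | canonical ±1/±2 dinucleotide altered/duplicated AND aberrant ≥ 0.95 | pathogenic |
| R2 | predicted nonsense/frameshift at DNA level AND aberrant ≥ 0.95 | pathogenic |
| R3 | aberrant ≥ 0.55 | likely pathogenic |
| R4 | aberrant ≥ 0.05 | uncertain (vus) |
| R5 | otherwise | not spliceogenic |

The 0.95 cut reflects that complete splice-site disruptions in this assay
class leave ≤5% canonical transcript; the 0.55 cut sits just under the
~60% aberrant level discussed in the clinical splicing literature as
marking severe splicing aberration. The table is monotone in the aberrant
fraction by construction (property-tested).

Prior evidence (an established protein-level classification) never
changes the splicing-viewpoint label; it upgrades the separate
`final_label` when the table says vus, and is always recorded in the
triggered rules. Keeping the two labels apart mirrors how assay cohorts
are reported: variants already classified on protein grounds are not
counted in the splicing-based pathogenic/likely-pathogenic lists, yet no
longer sit in the uncertain class. Cohort summaries count splicing-view
labels, final-vus, and prior upgrades separately.

Site classes are derived from position alone: `canonical_dinucleotide`
(any altered/duplicated intronic ±1/±2 of an annotated site — this covers
boundary-spanning deletions and splice-site duplications),
`splice_region` (last/first 3 exonic or 3–8 intronic bases), otherwise
`exonic`/`intronic`. The DNA-level coding prediction
(nonsense/frameshift/missense/synonymous/intronic) is an input, since it
requires the reference protein.

## The packaged cohort fixture

The *BRCA2* exons 14–20 construct and the 52-variant exon 17/18 cohort
ship as text fixtures. The outcome table (30 spliceogenic variants,
per-transcript percentages, reported r./p. strings) is transcribed
verbatim; transcribed percentages are renormalised to sum to exactly 1.
Three below-threshold variants are named with their measured aberrant
fractions; the remaining 19 negatives are not individually identified in
the available material and are shipped as clearly-labelled synthetic
placeholder rows (100% full-length) at the documented per-region split.
Exon c. anchors for the fixture are fixed by the printed boundary
variants and exon lengths (EX17 = c.7806–7976, EX18 = c.7977–8331, the
rest derived from the printed lengths).

Two transcription quirks are carried, not resolved: the outcome table
writes a two-position r. string (`r.7806_7807del`) for the 1-nt
acceptor-shift transcript (the engine emits `r.7806del`), and an
`ins6` shorthand where the engine emits the explicit intronic-range form.
The fixture keeps the printed strings as metadata; all computed
descriptions come from the engine.

The packaged PWMs are consensus-derived illustrative matrices built from
the motifs documented for this cohort (SF2/ASF `GATACGG`/`CAGAAGA`, SC35
`GGCTATAA`), labelled synthetic; published matrix sets drop into the same
YAML shape. PWM scoring is the standard additive per-position sum.

## Problem sizes and determinism

All shipped analyses are desk-scale: the full test suite runs in seconds,
and the acceptance script classifies the 52-variant cohort and applies
three event sets — its outputs are deterministic (the seed only drives a
simulated re-measurement exercise of the quantification path). Property
tests use seeded generators throughout; the oracle census covers 1,000
random construct/event cases at exon lengths 30–90 nt, which exercises
every event kind and both frame regimes.

## Known limitations

* Splicing outcomes are *inputs* (observed event sets), never predictions;
  the package deliberately contains no splice-site-strength or
  enhancer-gain models.
* p. strings for the real gene require the real CDS; the cohort fixture
  is length-only, so translation-path results are demonstrated on
  synthetic sequence and the fixture's reported p. strings are metadata.
* The r. grammar covers the event vocabulary (del / ins / delins /
  multi-alteration alleles); arbitrary HGVS is out of scope.
* The classifier codifies a splicing-viewpoint table with configurable
  thresholds; it is not a full ACMG/AMP evidence engine and ignores
  population frequency and segregation evidence by design.
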