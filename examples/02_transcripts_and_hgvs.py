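"""Splicing events -> transcript structures and HGVS r. descriptions.

Applies the aberrant splicing events seen in the assay cohort (skips,
alternative acceptors/donors, a retained intron fragment) and prints the
size change and standardized RNA-level description of each product.
"""

from minisplice.consequence import frame_status
from minisplice.fixtures import EVENT_CATALOG, load_construct
from minisplice.splice import apply_splice_events

construct = load_construct()

print(f"{'species':<28}{'Δnt':>6}  {'frame':<11}r. description")
for label, events in EVENT_CATALOG.items():
    t = apply_splice_events(construct, events, label=label)
    status, delta = frame_status(t)
    print(f"{label:<28}{delta:>+6}  {status:<11}{t.r_hgvs}")

# Each line is one transcript: e.g. exon-17 skipping removes 171 nt
# (r.7806_7976del, in frame), while exon-18 skipping removes 355 nt and
# shifts the reading frame.  Composites merge into a single contiguous
# deletion (r.7826_8331del) or a delins when an intron fragment is retained.
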