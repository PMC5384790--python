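"""Reporter-construct arithmetic: insert size and RT-PCR amplicons.

Loads the packaged BRCA2 exons 14-20 reporter and checks the numbers a
wet-lab validation would check: the cloned insert size and the product
sizes of the two standard primer pairs on the full-length transcript.
"""

from minisplice import amplicon_length, apply_splice_events, total_insert_length
from minisplice.fixtures import load_construct
from minisplice.splice import SpliceEvent

construct = load_construct()
fl = apply_splice_events(construct)          # canonical splicing
fwd_vec = construct.primer("SD6-PSPL3_RTFW")  # vector-exon forward
fwd_16 = construct.primer("RTBR2_ex16FW")     # exon-16 forward
rev = construct.primer("RTpSAD-RV")           # vector-exon reverse

print(f"construct: {construct.name}")
print(f"cloned insert: {total_insert_length(construct)} bp")
print(f"full-length amplicon (vector pair):  "
      f"{amplicon_length(fl, fwd_vec, rev)} nt")
print(f"full-length amplicon (exon-16 pair): "
      f"{amplicon_length(fl, fwd_16, rev)} nt")

skip17 = apply_splice_events(construct, {SpliceEvent("exon_skip", "EX17")})
print(f"exon-17-skipped amplicon (exon-16 pair): "
      f"{amplicon_length(skip17, fwd_16, rev)} nt")

# Expected output: insert 5837 bp; amplicons 1806 and 1012 nt; the skip
# product is exactly one exon length (171 nt) shorter, 841 nt -- the size
# shift by which the aberrant species is recognised on the electropherogram.
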