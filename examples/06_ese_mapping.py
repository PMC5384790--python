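"""Microdeletion design and splicing-enhancer motif mapping.

Designs the 10-nt microdeletion series used for functional enhancer
mapping of exon 18 (protected exon ends preserved), scans the documented
motif-bearing sequence with the packaged consensus PWMs, and intersects
hits with the deletion windows to find motifs shared by overlapping
spliceogenic deletions.
"""

from minisplice.construct import design_microdeletions
from minisplice.ese import map_hits_to_deletions, pwm_scan
from minisplice.fixtures import load_construct, load_reference_pwms

construct = load_construct()

deletions = design_microdeletions(construct, "EX18", window=10,
                                  targets=[(7979, 8008), (8004, 8033)])
print("exon-18 microdeletion series:")
for d in deletions:
    print(f"  {d.c_hgvs}")

# the enhancer-bearing 5' stretch of exon 18 around c.7979-8017, written
# out with the two SF2/ASF motifs (GATACGG, CAGAAGA) and the SC35 motif
# (GGCTATAA) at their documented coordinates
segment_start = 7979
exon18_5p = ("AT" + "GATACGG" + "ACTTCTTTCCTTT" + "CAGAAGA" + "GG"
             + "GGCTATAA" + "AT")
hits = pwm_scan(exon18_5p, load_reference_pwms(), c_anchor=segment_start)
print("\nmotif hits:")
for h in hits:
    print(f"  {h.pwm_name:<28} c.{h.c_start}_{h.c_end}  {h.sequence} "
          f"(score {h.score:.1f})")

table = map_hits_to_deletions(hits, deletions)
print("\nhits removed per deletion:")
for row in table.rows:
    removed = ", ".join(h.sequence for h in row.removed_hits) or "-"
    print(f"  {row.deletion.c_hgvs:<18} {removed}")
print("shared by overlapping deletions:",
      ", ".join(f"{h.sequence} (c.{h.c_start}_{h.c_end})"
                for h in table.shared_hits()))

# The CAGAAGA motif at c.8001-8007 falls inside both c.7999_8008del and
# c.8004_8013del -- a motif in the 5-nt overlap of two deletion windows is
# a strong candidate for the enhancer both deletions disrupt.
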