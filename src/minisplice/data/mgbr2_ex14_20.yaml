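# BRCA2 exons 14-20 splicing-reporter construct (MGBR2_ex14-20).
#
# Segment lengths follow the published construct description; shortened
# introns are listed as two pieces (the way the construct map prints them)
# and are merged by build_construct.  Exon c. anchors use the BRCA2 coding
# reference (NM_000059.1 numbering); intron and vector-exon segments carry
# lengths only.
#
# The vector-exon lengths and the per-primer tail splits are calibration
# constants, not measured values: only the sums enter any amplicon size.
# They are fixed so that the two standard RT-PCR reads give their known
# product sizes on the wild-type transcript:
#   V1 forward + V2 reverse over all seven exons (1,625 nt): 131 + 1625 + 50 = 1806
#   EX16 forward + V2 reverse (exons 17-20, 827 nt):          135 + 827 + 50 = 1012
name: MGBR2_ex14-20
segments:
  - {role: vector_exon, label: V1, length: 200}
  - {role: intron, label: IVS13, length: 328}   # printed as "IVS14" upstream of EX14
  - {role: exon, label: EX14, length: 428, c_start: 7008, c_end: 7435}
  - {role: intron, label: IVS14, length: 1139}
  - {role: exon, label: EX15, length: 182, c_start: 7436, c_end: 7617}
  - {role: intron, label: IVS15, length: 358}
  - {role: intron, label: IVS15b, length: 333}  # merged -> IVS15 (691)
  - {role: exon, label: EX16, length: 188, c_start: 7618, c_end: 7805}
  - {role: intron, label: IVS16, length: 234}
  - {role: intron, label: IVS16b, length: 181}  # merged -> IVS16 (415)
  - {role: exon, label: EX17, length: 171, c_start: 7806, c_end: 7976}
  - {role: intron, label: IVS17, length: 485}
  - {role: exon, label: EX18, length: 355, c_start: 7977, c_end: 8331}
  - {role: intron, label: IVS18, length: 314}
  - {role: intron, label: IVS18b, length: 235}  # merged -> IVS18 (549)
  - {role: exon, label: EX19, length: 156, c_start: 8332, c_end: 8487}
  - {role: intron, label: IVS19, length: 398}
  - {role: exon, label: EX20, length: 145, c_start: 8488, c_end: 8632}
  - {role: intron, label: IVS20, length: 207}
  - {role: vector_exon, label: V2, length: 100}
primers:
  - {name: SD6-PSPL3_RTFW, segment: V1, offset_from_segment_end: 131, direction: forward}
  - {name: RTBR2_ex16FW, segment: EX16, offset_from_segment_end: 135, direction: forward}
  - {name: RTpSAD-RV, segment: V2, offset_from_segment_end: 50, direction: reverse}
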