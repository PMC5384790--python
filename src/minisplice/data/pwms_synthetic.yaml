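# Illustrative SR-protein PWMs, consensus-derived (synthetic stand-ins).
#
# These matrices are built from the named example binding sequences with a
# +1 match / -1 mismatch scheme, NOT from any published matrix set; they
# exist so the scanning machinery has working defaults and so the
# documented enhancer motifs of BRCA2 exon 18 (SF2/ASF sites GATACGG at
# c.7981-7987 and CAGAAGA at c.8001-8007; an SC35 site GGCTATAA at
# c.8010-8017) are recovered on matching sequence. Replace with published
# matrices (same YAML shape) for real scoring.
pwms:
  - name: SF2/ASF (consensus, synthetic)
    threshold: 5.0
    # columns from GATACGG and CAGAAGA; degenerate positions admit both
    matrix:
      - {A: -1.0, C: 1.0, G: 1.0, T: -1.0}   # G/C
      - {A: 1.0, C: -1.0, G: -1.0, T: -1.0}  # A
      - {A: -1.0, C: -1.0, G: 1.0, T: 1.0}   # T/G
      - {A: 1.0, C: -1.0, G: -1.0, T: -1.0}  # A
      - {A: 1.0, C: 1.0, G: -1.0, T: -1.0}   # C/A
      - {A: -1.0, C: -1.0, G: 1.0, T: -1.0}  # G
      - {A: 1.0, C: -1.0, G: 1.0, T: -1.0}   # G/A
  - name: SC35 (consensus, synthetic)
    threshold: 8.0
    # columns from GGCTATAA (exact-match matrix)
    matrix:
      - {A: -1.0, C: -1.0, G: 1.0, T: -1.0}
      - {A: -1.0, C: -1.0, G: 1.0, T: -1.0}
      - {A: -1.0, C: 1.0, G: -1.0, T: -1.0}
      - {A: -1.0, C: -1.0, G: -1.0, T: 1.0}
      - {A: 1.0, C: -1.0, G: -1.0, T: -1.0}
      - {A: -1.0, C: -1.0, G: -1.0, T: 1.0}
      - {A: 1.0, C: -1.0, G: -1.0, T: -1.0}
      - {A: 1.0, C: -1.0, G: -1.0, T: -1.0}
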