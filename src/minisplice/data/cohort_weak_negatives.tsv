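variant	motif	coding_prediction	outcomes	notes
c.7875A>G	ESE/ESS	missense	FL=95.3;others=4.7	below-threshold splicing impact (4.7% aberrant)
c.7985C>T	ESE/ESS	missense	FL=96.7;others=3.3	below-threshold splicing impact (3.3% aberrant)
c.8042C>G	ESE/ESS	missense	FL=97.7;others=2.3	below-threshold splicing impact (2.3% aberrant)
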