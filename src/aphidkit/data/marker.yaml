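# Packaged cytb-16S marker definition for A. gossypii biotyping.
# Primers are the published CytbF/16SR pair; the diagnostic offsets and the
# flanked reference fragments are SYNTHETIC (the real amplicon coordinates
# are not published) -- real-data users must supply their own offsets.
forward_primer: TACCATGAGGACAAATATCATTTTGA
reverse_primer: AAGGGACGATAAGACCCTATAAAAC
offsets: [20, 45, 70, 95, 120]
cotton_pattern: TAATT
cucumber_pattern: CGGCC
max_primer_mismatches: 2
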