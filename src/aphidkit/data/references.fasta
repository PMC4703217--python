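>cotton_reference_synthetic synthetic cytb-16S marker amplicon, TAATT at diagnostic offsets
TACCATGAGGACAAATATCATTTTGATCTTATTTACCTGTCAGATGTCTTTACAATTTACCAACATCTTA
TACATAAATTTTCGAATCGTGGGAACACTAAAATGTTCTAAATCAGATCCATCAATTTATTTCAATCAAG
ATTTCGTGACACAAAGATGAGATCTACCTGCAAGCAGTTTTATAGGGTCTTATCGTCCCTT
>cucumber_reference_synthetic synthetic cytb-16S marker amplicon, CGGCC at diagnostic offsets
TACCATGAGGACAAATATCATTTTGATCTTATTTACCTGTCAGATGCCTTTACAATTTACCAACATCTTA
TGCATAAATTTTCGAATCGTGGGAACGCTAAAATGTTCTAAATCAGATCCACCAATTTATTTCAATCAAG
ATTTCGCGACACAAAGATGAGATCTACCTGCAAGCAGTTTTATAGGGTCTTATCGTCCCTT
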