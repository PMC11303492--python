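>TIE2_L914F_synthetic synthetic amplicon context framed by the TIE2 genotyping primers; not genomic TEK sequence
CAGGGCCACTGATGAGTCGATACCTGGTAGCGATCTGGCATTGACAGGTTCTTGAGCCTAACCATGAGTACTTGACCAGTACTCCTTCACTTCGCTGCCGA
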