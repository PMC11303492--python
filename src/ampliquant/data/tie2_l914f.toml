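# TIE2 L914F knock-in quantification config (synthetic amplicon context).
# The donor edit is the canonical c.2740C>T change (CTT -> TTT, Leu914Phe),
# at 0-based position 9 of the editing window.
[amplicon]
amplicon_id = "TIE2_L914F_synthetic"
fasta = "tie2_synthetic.fa"
left_flank = "GATCTGGCAT"
right_flank = "CCATGAGTAC"
window = "TGACAGGTTCTTGAGCCTAA"
donor_edits = ["9:C>T"]
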