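# Simulation recipe emulating a selection-enriched knock-in pool:
# 98.5% precise edit, 1.0% indel (4-bp deletion), 0.5% wild type,
# 20,000 full-amplicon reads at a 0.001/base substitution error rate.
[amplicon]
amplicon_id = "TIE2_L914F_synthetic"
fasta = "tie2_synthetic.fa"
left_flank = "GATCTGGCAT"
right_flank = "CCATGAGTAC"
window = "TGACAGGTTCTTGAGCCTAA"
donor_edits = ["9:C>T"]

[[alleles]]
label = "HDR"
kind = "HDR"
proportion = 0.985

[[alleles]]
label = "DEL4"
kind = "INDEL"
proportion = 0.010
position = 10
delta = -4

[[alleles]]
label = "WT"
kind = "WT"
proportion = 0.005

[pool]
n_reads = 20000
error_rate = 0.001
seed = 1
quality = 30
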