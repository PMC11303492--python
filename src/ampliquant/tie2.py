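"""Bundled TIE2 (TEK) L914F amplicon fixture — synthetic context.

The amplicon is framed by the TIE2 genotyping primers
(F: CAGGGCCACTGATGAGTCGAT, R: TCGGCAGCGAAGTGAAGGAG). The donor edit is
the canonical venous-malformation variant c.2740C>T, which converts the
leucine-914 codon CTT to the phenylalanine codon TTT — a single C>T
substitution inside the editing window. The sequence *between* the
primers, including the 10-bp flank anchors and the 20-bp editing window
around the codon, is a synthetic stand-in chosen to satisfy the anchor
uniqueness constraints; it is not the genomic TEK sequence, so treat the
fixture as a demonstration/simulation reference, not a genotyping
reference.
"""

from __future__ import annotations

from .amplicon import AmpliconSpec, DonorEdit, revcomp

__all__ = ["tie2_l914f_spec", "F_TIE2", "R_TIE2"]

#: genotyping PCR primers for the TIE2 locus
F_TIE2 = "CAGGGCCACTGATGAGTCGAT"
R_TIE2 = "TCGGCAGCGAAGTGAAGGAG"

_LEFT_FLANK = "GATCTGGCAT"
# editing window: L914 codon CTT at positions 9-11; c.2740C>T edits position 9
_WINDOW = "TGACAGGTTCTTGAGCCTAA"
_RIGHT_FLANK = "CCATGAGTAC"

_AMPLICON = (
    F_TIE2
    + "ACCTGGTAGC"
    + _LEFT_FLANK
    + _WINDOW
    + _RIGHT_FLANK
    + "TTGACCAGTA"
    + revcomp(R_TIE2)
)


def tie2_l914f_spec() -> AmpliconSpec:
    """AmpliconSpec for the synthetic TIE2 L914F knock-in fixture."""
    return AmpliconSpec(
        amplicon_id="TIE2_L914F_synthetic",
        amplicon_seq=_AMPLICON,
        left_flank=_LEFT_FLANK,
        right_flank=_RIGHT_FLANK,
        donor_edits=(DonorEdit(window_pos=9, ref_base="C", alt_base="T"),),
    )
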