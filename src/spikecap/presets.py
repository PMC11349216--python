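"""Published reagent sequences for the nc886 capture design.

nc886 is a 102-nt RNA polymerase III transcript without a polyA tail.  The
capture oligo combines the 10x Read2N adaptor, the TotalSeq-C0182 feature
barcode, and a 20-nt anchor reverse-complementary to the nc886 3' region,
with 10- and 9-nt randomized spacers between the blocks.
"""

from __future__ import annotations

from spikecap.design import GSPDesign, ReadAnatomy, TargetGene, parse_gsp

# Reference transcript (RNA as published; normalized to DNA by TargetGene).
NC886_RNA = (
    "CGGGUCGGAGUUAGCUCAAGCGGUUACCUCCUCAUGCCGGACUUUCUAUCUGUCCAUCUCUGUGCUGGGG"
    "UUCGAGACCCGCGGGUGCUUACUGACCCUUUU"
)

READ2N_ADAPTOR = "CGGAGATGTGTATAAGAGACAG"
TOTALSEQ_C0182_BARCODE = "GTATGTCCGCTCGAT"
NC886_ANCHOR = "AGGGTCAGTAAGCACCCGCG"

# Full GSP oligo 5'->3' with randomized spacer positions as N's.
NC886_GSP_OLIGO = (
    READ2N_ADAPTOR + "N" * 10 + TOTALSEQ_C0182_BARCODE + "N" * 9 + NC886_ANCHOR
)


def nc886_target() -> TargetGene:
    """The nc886 reference as a :class:`TargetGene` (no masks applied)."""
    return TargetGene(name="nc886", sequence=NC886_RNA)


def nc886_design(target: TargetGene | None = None) -> GSPDesign:
    """The published nc886 GSP, parsed from the oligo and anchored on nc886."""
    design = parse_gsp(NC886_GSP_OLIGO, READ2N_ADAPTOR, TOTALSEQ_C0182_BARCODE)
    return design.locate_anchor(target if target is not None else nc886_target())


def chromium_5p_anatomy() -> ReadAnatomy:
    """10x Chromium 5' read anatomy (16-nt CB, 10-nt UMI, 13-nt TSO)."""
    return ReadAnatomy()
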