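accession,species,role,partner
ALB_HUMAN_SURR,human,analyte,
ALB_BOVIN_SURR,bovine,internal_standard,ALB_HUMAN_SURR
LACT_HUMAN_SURR,human,analyte,
LACT_BOVIN_SURR,bovine,internal_standard,LACT_HUMAN_SURR
LYS_HUMAN_SURR,human,analyte,
LYS_CHICK_SURR,chicken,internal_standard,LYS_HUMAN_SURR
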