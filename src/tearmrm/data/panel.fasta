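>ALB_HUMAN_SURR synthetic surrogate, human albumin signature context
MKLVNEVTEFAKAGDLTEYR
>ALB_BOVIN_SURR synthetic surrogate, bovine albumin (IS) signature context
MKLVNELTEFAKSGDVAEHR
>LACT_HUMAN_SURR synthetic surrogate, human lactoferrin signature context
MKLRPVAAEVYGTERGGSDSAHK
>LACT_BOVIN_SURR synthetic surrogate, bovine lactoferrin (IS) signature context
MKLRPVAAEIYGTKGGNDSTHK
>LYS_HUMAN_SURR synthetic surrogate, human lysozyme signature context
MKSTDYGIFQINSRAGVDSSHK
>LYS_CHICK_SURR synthetic surrogate, chicken lysozyme (IS) signature context
MKFESNFNTQATNRAGIESSHK
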