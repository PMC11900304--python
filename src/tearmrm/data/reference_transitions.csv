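protein,peptide,precursor_mz,precursor_charge,product_mz,fragment_annotation,collision_energy,retention_time_min,quantifier
Albumin,LVNEVTEFAK,575.3,2,595.3,y5,25,9.85,true
Albumin,LVNEVTEFAK,575.3,2,694.4,y6,20,9.85,false
IS Albumin,LVNELTEFAK,582.3,2,708.4,y6,25,10.28,true
IS Albumin,LVNELTEFAK,582.3,2,837.4,y7,20,10.28,false
Lactoferrin,LRPVAAEVYGTER,487.6,3,462.2,y4,20,8.80,true
Lactoferrin,LRPVAAEVYGTER,487.6,3,737.4,b7,20,8.80,false
IS Lactoferrin,LRPVAAEIYGTK,659.3,2,737.4,b7,20,9.52,true
IS Lactoferrin,LRPVAAEIYGTK,659.3,2,850.5,b8,20,9.52,false
Lysozyme,STDYGIFQINSR,700.8,2,764.4,y6,25,10.11,true
Lysozyme,STDYGIFQINSR,700.8,2,304.1,b3,25,10.11,false
IS Lysozyme,FESNFNTQATNR,714.8,2,1152.5,y10,25,8.18,true
IS Lysozyme,FESNFNTQATNR,714.8,2,804.3,y7,25,8.18,false
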