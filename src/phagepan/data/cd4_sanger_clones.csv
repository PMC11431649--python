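peptide,clone_count
HFYGPGP,8
HGHSGYL,8
HFQHSHT,5
EPHSHHH,3
HYTAPYQ,3
SHWRNPS,2
RLSAPAW,2
SILSRLG,2
QNNIHTP,2
WSLGYTG,2
GYRLPDA,1
YPLVGHF,1
NPPMAVE,1
LPYLHEH,1
QTFTLAT,1
SWTVWRS,1
WHWPLTV,1
QHNLTSR,1
HPSTWHK,1
SKLHLAP,1
QFPKNPQ,1
SLIGSNR,1
WSAKLYI,1
DPGFRGT,1
YSVTKLH,1
IAKLPRM,1
MHMTNMI,1
HGKILLT,1
VLGSHEW,1
SLFLVGP,1
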