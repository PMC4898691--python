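>AtBBE28_ref_synthetic synthetic stand-in for AtBBE-like 28 (At5g44440); type-IIa diagnostic residues at reference positions, scaffold is pseudo-random
IMFPKHSDLGNWSCQDTFFKIMRDDSAQFEDYWRRQWYLHAPNWHIGGIYHNKLYCIWMD
CEGFYDAPFWAACETCRDFVKDAMFGKLEPTTHCIWDAGQQGQLEAISGGHDYGAEIWFD
HDCFWHNWWGSCRDNQRKDKELVRNKTSTWYYWGCVTWNDRFDCCDQCCKTGGHLWVTFY
SQPCDWIYMDWIPVWGMQCVGDMWGRLYLIFCEKVCTTENPKQIHSMNHWGVCSWEQWHI
HWRGVKAAIQYWCEWRKRRGHTYHIACMIKEGSVLWSSMLEMQIEFPWEHTKEPWIVIVY
DAWAKEISETMWPGMWFFNWPYKSIKNAGMGPVGNWAVEVRTWMVLFSGNTSKLLMKSIY
QCVGYDIVDFYPFYNGWFKQCTVPRQHDHLTRSIEWMQHTSQQMDRAYYKIWTSEPVYPH
KIHRVERQEQEEQAKSCHFFYTEKHSYQHNKYEVKYHYYKPDRELSTRPYTSFPGSFAFM
NQNHSYERAFKINHKAWPYH
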