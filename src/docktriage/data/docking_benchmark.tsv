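label	rmsd
Chem PLP (reference)	6.547
PLP (reference)	1.037
PLP95 (reference)	0.979
Autodock Vina (reference)	0.846
Vinardo (reference)	0.918
Chem PLP (radius)	0.775
PLP (radius)	0.765
PLP95 (radius)	1.004
Autodock Vina (radius)	0.795
Vinardo (radius)	0.969
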