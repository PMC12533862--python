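compound	window_median	is_inhibitor
Empagliflozin	1.54	1
Ceftriaxone	1.62	0
Dapagliflozin	1.66	1
Tobramycin	1.69	0
Raltitrexed	1.78	0
Canagliflozin	1.80	1
Ertugliflozin	1.91	1
Clindamycin	1.99	0
Ribavirin	2.07	0
Fluvastatin	2.62	0
Timolol	2.88	0
Atorvastatin	3.23	0
Ticagrelor	3.24	0
Calcitriol	3.62	0
Fostamatinib	4.91	0
Theophylline	4.96	0
Carbocisteine	5.06	0
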