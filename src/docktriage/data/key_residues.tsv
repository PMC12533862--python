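chain	resnum	resname
A	75	ASN
A	80	HIS
A	87	THR
A	98	PHE
A	99	GLU
A	287	SER
A	290	TYR
A	321	LYS
A	457	GLN
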