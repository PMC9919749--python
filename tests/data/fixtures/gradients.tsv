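# sipscreen output
# bundle: sipscreen-fixture-v1
# seed: 20230211
gradient_id	treatment	prey	timepoint	target
C13_E_coli_1d	C13	E_coli	1d	prok_16S
C12_E_coli_1d	C12	E_coli	1d	prok_16S
C13_E_coli_2d	C13	E_coli	2d	prok_16S
C12_E_coli_2d	C12	E_coli	2d	prok_16S
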