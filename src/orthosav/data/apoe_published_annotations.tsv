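variant	label	allele_frequency	conservation
C130R	pathogenic	0.138	.
R163C	.	0.001	.
R132C	.	0.00003	.
R163P	.	.	.
R160C	.	.	.
L46P	conflicting	0.0025	.
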