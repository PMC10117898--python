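variant	ESM	DynaMut	Missense3D	AlphaFold
C130R	0	-1.07	1	33.813
R163C	9.631	-0.86	0	8.305
R132C	8.259	-0.77	1	5.664
R163P	10.296	-0.48	0	9.320
R160C	9.571	-0.02	0	9.113
L46P	3.106	-0.09	0	3.564
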