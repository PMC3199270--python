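gene	model	lnL	np	omega	p0	p1	p2	w0	w1	w2	beta_p	beta_q
MAT1-1-1	M0	-2205.4733		0.4280
MAT1-1-1	M3	-2202.4940		0.4462	0.3732	0.3932	0.2336	0.7052	0.1117	0.7052
MAT1-1-1	M1a	-2202.6642		0.4599	0.6556	0.3440		0.1761	1
MAT1-1-1	M2a	-2202.6642		0.4599	0.6556	0.2332	0.1109	0.1761	1	1
MAT1-1-1	M7	-2202.5615		0.4507							0.4117	0.5019
MAT1-1-1	M8	-2202.5615		0.4507	0.1000	0.00001			1.0000		0.4117	0.5019
MAT1-1-3	M0	-1706.3379		0.2951
MAT1-1-3	M3	-1696.0792		0.3103	0.0007	0.9232	0.0761	0.1116	0.1117	2.7212
MAT1-1-3	M1a	-1697.3663		0.2598	0.7402	0.2598		0	1
MAT1-1-3	M2a	-1696.0792		0.3103	0.9239	0	0.0761	0.1117	1	2.7212
MAT1-1-3	M7	-1697.6108		0.3000							0.0050	0.0119
MAT1-1-3	M8	-1696.0811		0.3104	0.9244	0.0756			2.7290		12.5791	99.0000
MAT1-2-1	M0	-2133.8605		0.37135
MAT1-2-1	M3	-2128.2767		0.4212	0.3531	0.6157	0.0312	0.2495	0.2496	5.7427
MAT1-2-1	M1a	-2129.6740		0.3528	0.6472	0.3528		0	1
MAT1-2-1	M2a	-2128.2767		0.4212	0.9688	0	0.0312	0.2496	1	5.7428
MAT1-2-1	M7	-2129.8169		0.3387							0.0170	0.0321
MAT1-2-1	M8	-2128.2769		0.4212	0.9690	0.0310			5.7612		33.0717	99.0000
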