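id	acronym	name	parent_id	r	g	b	volume_mm3	oversaturated
1	ROOT	whole brain		0	0	0	0	0
2	CTX	cortex	1	10	120	40	0	0
3	HIP	hippocampal region	1	20	80	200	0	0
4	STR	striatum	1	200	60	30	0	0
5	MOp	primary motor area	2	30	140	60	4.5	0
6	SSp	primary somatosensory area	2	40	150	70	6.0	0
7	VISp	primary visual area	2	50	160	80	3.2	0
8	CA1	cornu ammonis 1	3	60	90	210	5.1	0
9	DG	dentate gyrus	3	70	100	220	2.8	0
10	CP	caudoputamen	4	210	70	40	9.4	0
11	ACB	nucleus accumbens	4	220	80	50	2.1	0
12	GPe	globus pallidus external	4	230	90	60	1.3	0
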