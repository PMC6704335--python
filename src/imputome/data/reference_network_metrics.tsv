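gender	group	nodes	edges	density	diameter	centralization	clustering_coefficient
F	Vata	2030	25506	0.006	16	0.041	0.262
F	Pitta	1338	18496	0.103	9	0.07	0.372
F	Kapha	3285	291052	0.026	32	0.09	0.355
M	Vata	2050	35112	0.008359104	17	0.05071883	0.3448578
M	Pitta	2117	43704	0.009756289	22	0.07250859	0.2802401
M	Kapha	973	9220	0.009748815	8	0.08086928	0.29
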