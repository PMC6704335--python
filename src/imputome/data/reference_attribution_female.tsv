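taxon	category	avg_attribution_of_function	avg_attribution_of_total	total_avg_attribution
Actinobacteria	Cellular Processes	0.27	0.01	0.29
Actinobacteria	Environmental Information Processing	0.29	0.05	0.29
Actinobacteria	Genetic Information Processing	0.28	0.08	0.29
Actinobacteria	Metabolism	0.26	0.1	0.29
Actinobacteria	Unclassified	0.3	0.05	0.29
Bacteroidetes	Cellular Processes	25.54	1.01	32.25
Bacteroidetes	Environmental Information Processing	22.3	3.16	32.25
Bacteroidetes	Genetic Information Processing	34.38	9.93	32.25
Bacteroidetes	Metabolism	35.26	12.83	32.25
Bacteroidetes	Unclassified	32.63	5.32	32.25
Firmicutes	Cellular Processes	72.88	3.15	65.94
Firmicutes	Environmental Information Processing	75.58	12.09	65.94
Firmicutes	Genetic Information Processing	63.76	17.87	65.94
Firmicutes	Metabolism	63.05	22.13	65.94
Firmicutes	Unclassified	65.56	10.7	65.94
Fusobacteria	Cellular Processes	0.05	0.01	0.13
Fusobacteria	Environmental Information Processing	0.06	0.02	0.13
Fusobacteria	Genetic Information Processing	0.03	0.03	0.13
Fusobacteria	Metabolism	0.04	0.05	0.13
Fusobacteria	Unclassified	0.05	0.02	0.13
Lentisphaerae	Cellular Processes	0.11	0.02	0.59
Lentisphaerae	Environmental Information Processing	0.1	0.07	0.59
Lentisphaerae	Genetic Information Processing	0.14	0.17	0.59
Lentisphaerae	Metabolism	0.15	0.21	0.59
Lentisphaerae	Unclassified	0.18	0.12	0.59
Proteobacteria	Cellular Processes	1.05	0.04	1.33
Proteobacteria	Environmental Information Processing	1.61	0.25	1.33
Proteobacteria	Genetic Information Processing	1.34	0.39	1.33
Proteobacteria	Metabolism	1.2	0.44	1.33
Proteobacteria	Unclassified	1.24	0.21	1.33
Spirochaetes	Cellular Processes	0.06	0.03	0.31
Spirochaetes	Environmental Information Processing	0.05	0.07	0.31
Spirochaetes	Genetic Information Processing	0.03	0.08	0.31
Spirochaetes	Metabolism	0.03	0.09	0.31
Spirochaetes	Unclassified	0.03	0.04	0.31
Tenericutes	Cellular Processes	0.02	0	0.04
Tenericutes	Environmental Information Processing	0.01	0.01	0.04
Tenericutes	Genetic Information Processing	0.03	0.02	0.04
Tenericutes	Metabolism	0.01	0.01	0.04
Tenericutes	Unclassified	0.01	0	0.04
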