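gene	eev_trisomic	eev_euploid	expected_ratio	observed_ratio
RCAN1	453.79	263.66	1.72	0.98
SDC2	437.68	823.53	0.53	1.14
SERPINF1	194.90	328.31	0.59	0.41
SOD1	2937.37	1845.43	1.59	2.00
POSTN	373.55	1866.22	0.20	0.82
BACE2	191.80	95.41	2.01	1.25
ACTB	5048.13	4775.04	1.06	0.37
ADAMTS1	1132.72	552.20	2.05	1.27
ATP5J	1459.89	944.98	1.54	1.64
DHFR	151.07	51.51	2.93	1.84
DONSON	107.93	45.93	2.35	1.96
DYRK1A	120.45	87.71	1.37	1.30
MX1	446.86	52.12	8.57	4.65
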