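symbol	function	zebrafish_fc	zebrafish_log_cpm	zebrafish_fdr	bichir_fc	bichir_log_cpm	axolotl_fc	axolotl_log_cpm
fgf20a	FGF signaling	20.90	3.27	9.08e-52	8.97	1.87	1.80	1.49
igf2b	IGF signaling	3.84	6.28	5.52e-20	3.00	3.12	1.96	4.16
erbb2	Cell proliferation	-2.19	6.03	3.10e-19	-1.26	5.80	-1.23	6.02
ttk	Cell proliferation	3.76	3.79	1.79e-17	100	2.95	1.84	4.06
junbb	Cell proliferation	2.59	6.91	1.28e-06	5.30	8.46	8.49	7.51
smarca4	Transcriptional coactivator	2.28	7.04	1.11e-17	2.50	5.34	2.29	5.18
mmp9	Proteolysis of ECM	2.33	6.98	2.03e-10	44.11	9.24	81.25	10.75
mmp14a	Positive regulator of cell growth	3.18	7.80	8.56e-31	3.39	8.80	3.18	8.76
timp2a	MMP Inhibitor	2.40	8.98	3.52e-18	1.37	7.71	1.36	7.63
cxcl12a	Chemokine	-3.66	6.88	6.90e-17	-3.07	2.36	-6.30	2.48
hspd1	Stress response	1.69	7.07	9.24e-05	1.62	7.28	3.33	7.87
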