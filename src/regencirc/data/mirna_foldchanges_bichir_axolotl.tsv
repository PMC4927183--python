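symbol	bichir_log2fc	axolotl_log2fc
miR-451	3.36	5.88
miR-21	1.85	5.21
miR-203a	1.12	4.39
miR-223	4.09	3.30
miR-142a	2.05	3.16
miR-31	5.18	2.96
miR-7b	4.26	2.14
miR-181c	2.43	2.13
let-7b	2.91	2.04
miR-200	1.45	2.04
miR-155	3.02	1.99
miR-92a	1.20	1.82
miR-196a	1.77	1.67
miR-193b	3.38	1.67
miR-181b	1.17	1.64
miR-221	5.89	1.56
miR-146a	0.59	1.20
miR-34a	2.08	1.06
miR-1788	0.69	0.93
miR-2188	6.17	0.83
miR-19a	0.83	0.66
miR-26a	-2.05	-0.67
miR-33a	-1.87	-0.71
miR-27b	-2.07	-0.72
miR-24	-1.41	-0.73
miR-34c	-1.77	-0.97
miR-460	-4.90	-0.98
miR-458	-7.15	-1.06
miR-106a	-1.41	-1.14
miR-192	-2.30	-1.15
miR-16b	-0.98	-1.20
let-7c	-2.30	-1.31
miR-217	-3.33	-1.31
miR-338	-2.90	-1.57
miR-218b	-1.85	-1.58
miR-145	-1.90	-1.70
miR-2184	-2.25	-2.50
miR-206	-6.11	-3.26
miR-140	-3.06	-3.68
miR-499	-4.55	-4.21
miR-133a	-4.25	-5.07
miR-152	-2.53	-8.27
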