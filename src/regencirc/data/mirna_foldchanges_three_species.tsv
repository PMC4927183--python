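symbol	section	zebrafish_log2fc	zebrafish_p	bichir_log2fc	axolotl_log2fc
miR-21	all_three	4.05	3.28e-8	1.85	5.21
miR-181c	all_three	2.88	2.41e-6	2.43	2.13
miR-181b	all_three	2.29	2.52e-4	1.17	1.64
miR-31	all_three	2.02	6.14e-4	5.18	2.96
miR-7b	all_three	1.50	2.0e-2	4.26	2.14
miR-2184	all_three	-2.63	2.54e-5	-2.25	-2.50
miR-24	all_three	-1.36	1.9e-2	-1.41	-0.73
miR-133a	all_three	-1.72	2.67e-3	-4.25	-5.07
miR-338	all_three	-2.23	1.90e-4	-2.90	-1.57
miR-204	all_three	-2.60	4.76e-5	-0.57	-2.36
miR-218a	zebrafish_bichir	2.72	9.75e-6	1.23
miR-15b	zebrafish_bichir	2.06	5.92e-4	1.62
miR-210	zebrafish_bichir	1.91	1.91e-3	1.34
miR-16a	zebrafish_bichir	1.90	1.16e-3	0.99
miR-132	zebrafish_bichir	1.83	1.71e-3	0.52
miR-222a	zebrafish_bichir	1.54	1.13e-2	3.24
miR-454b	zebrafish_bichir	1.14	4.93e-2	0.14
miR-101b	zebrafish_bichir	-2.52	3.44e-5	-3.43
miR-26b	zebrafish_bichir	-1.91	1.84e-3	-3.67
miR-203b	zebrafish_bichir	-1.77	3.45e-3	-0.21
miR-10b	zebrafish_bichir	-1.36	2.90e-2	-1.78
miR-725	zebrafish_bichir	-1.29	3.23e-2	-1.62
miR-27a	zebrafish_axolotl	1.57	7.96e-3		2.15
miR-29b	zebrafish_axolotl	-2.05	1.28e-2		-0.97
miR-27b	zebrafish_only	1.38	2.44e-2
miR-143	zebrafish_only	1.31	2.89e-2
miR-30e	zebrafish_only	1.18	4.80e-2
miR-200c	zebrafish_only	-1.85	1.72e-3
miR-200a	zebrafish_only	-1.74	3.66e-3
miR-23a	zebrafish_only	-1.35	2.05e-2
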