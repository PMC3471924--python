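gene	ld_sensitive	hd_sensitive	ld_resistant	hd_resistant
Hist1h2ad	-1.23	-1.84	ns	-1.25
Mpeg1	-1.18	-1.13	ns	-1.13
Fbn2	-1.11	-1.66	ns	-1.08
H19	-1.01	-1.56	ns	-1.68
Cdt1	-0.94	-1.14	ns	-0.99
Clec7a	-0.92	-1.41	ns	-1.19
Mcm5	-0.89	-1.15	ns	-0.60
Irf8	-0.87	-1.06	ns	-0.71
Cdt1	-0.85	-1.11	ns	-0.75
Stmn1	-0.84	-1.48	ns	-1.11
Lst1	-0.81	-1.12	ns	-0.58
Uhrf1	-0.71	-1.13	ns	-0.84
Col9a1	-0.71	-1.82	ns	-0.89
Irf8	-0.70	-1.53	ns	-1.07
Fyb	-0.69	-1.04	ns	-1.02
Tlr1	-0.69	-0.72	ns	-0.60
Mcm6	-0.69	-1.02	ns	-1.18
Gzma	-0.68	-1.08	ns	-0.89
Cybb	-0.66	-0.98	ns	-0.66
Ptprc	-0.64	-1.21	ns	-1.00
Ccl5	-0.61	-0.79	ns	-0.91
Copg2as2	0.65	0.85	ns	0.82
Fbxo21	0.66	0.62	ns	1.08
Anxa8	0.69	1.04	ns	0.63
Zbtb16	0.70	1.13	ns	0.90
Zbtb16	0.76	1.13	ns	0.74
Cdh13	0.96	0.84	ns	0.63
Zbtb16	1.19	1.46	ns	1.10
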