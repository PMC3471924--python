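gene	probe_id	p_value	category	lower_in_above_median
MAGOHB	218894_s_at	7.39E-05	rna_processing	0
PAPOLA	212720_at	8.98E-06	rna_processing	0
PNPT1	225291_at	5.46E-10	rna_processing	0
POP4	202868_s_at	1.99E-03	rna_processing	0
PPIH	204228_at	1.77E-05	rna_processing	0
RBM39	208720_s_at	9.41E-05	rna_processing	0
RPS6	209134_s_at	4.64E-03	rna_processing	1
SUPT16H	233827_s_at	7.69E-05	rna_processing	0
TXNL4A	202836_s_at	5.81E-07	rna_processing	0
EIF2S1	201144_s_at	1.75E-07	stress_response	0
GNA13	224761_at	7.16E-09	stress_response	0
GNB1	200744_s_at	8.14E-05	stress_response	0
HLA-DRA	208894_at	2.33E-05	stress_response	0
PRDX2	215067_x_at	3.39E-04	stress_response	1
PRDX3	209766_at	4.39E-03	stress_response	1
RAD23A	201039_s_at	2.33E-04	stress_response	0
RPS6	209134_s_at	4.64E-03	stress_response	1
RUNX1	210365_at	4.85E-06	stress_response	1
SMC6	218781_at	2.95E-05	stress_response	0
SUPT16H	233827_s_at	7.69E-05	stress_response	0
ABCB10	223320_s_at	3.50E-03	other	0
ABCF1	200045_at	1.04E-09	other	0
BAT5	224756_s_at	2.01E-06	other	0
BMP2K	37170_at	6.77E-03	other	1
C17orf95	225808_at	5.28E-08	other	0
C19orf56	217780_at	1.64E-03	other	0
C5orf22	203738_at	5.40E-03	other	0
CAP1	213798_s_at	7.70E-06	other	0
CBX7	212914_at	2.68E-04	other	1
CHCHD3	217972_at	5.68E-07	other	0
CHCHD4	229595_at	1.90E-05	other	0
CLASP2	212308_at	8.48E-03	other	1
CLDND1	208925_at	1.06E-04	other	0
DDX19A	202578_s_at	1.52E-05	other	0
DNAJC10	221781_s_at	9.41E-12	other	0
GADD45GIP1	212891_s_at	2.13E-03	other	0
GBP1	202270_at	1.17E-05	other	0
HLA-B	208729_x_at	9.92E-06	other	0
KIF5B	224662_at	2.39E-05	other	0
MCART1	232092_at	1.86E-06	other	0
MCM6	201930_at	1.79E-07	other	0
MTFR1	203207_s_at	1.79E-07	other	0
NRD1	208709_s_at	4.64E-08	other	0
PDK1	206686_at	5.81E-06	other	0
PDXDC1	212053_at	1.30E-05	other	0
PEBP1	211941_s_at	9.61E-05	other	0
PHF20	235389_at	1.62E-03	other	0
PI4K2B	222631_at	1.87E-11	other	0
PIGO	209998_at	5.92E-03	other	0
PPME1	217841_s_at	2.47E-04	other	0
RAB6B	221792_at	1.08E-04	other	1
SAPS3	222467_s_at	3.76E-06	other	0
SCAND1	231059_x_at	3.21E-08	other	0
SHC1	201469_s_at	2.47E-03	other	0
SLC15A2	240159_at	6.86E-03	other	1
SNX6	222410_s_at	5.35E-12	other	0
TM2D2	224413_s_at	3.83E-08	other	0
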