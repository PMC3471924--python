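gene	probe_id	p_value	category	lower_in_above_median
CAD	202715_at	2.63E-03	mitosis	0
CCNK	225824_at	2.07E-03	mitosis	0
CDC7	204510_at	4.27E-06	mitosis	0
CDT1	228868_x_at	1.21E-08	mitosis	0
CENPH	231772_x_at	1.45E-04	mitosis	0
CHEK1	205393_s_at	6.03E-09	mitosis	0
EZH2	203358_s_at	8.18E-12	mitosis	0
GINS1	206102_at	2.95E-07	mitosis	0
HELLS	220085_at	3.39E-04	mitosis	0
MCM2	202107_s_at	8.02E-07	mitosis	0
MCM3	201555_at	6.17E-05	mitosis	0
MCM4	212141_at	5.50E-07	mitosis	0
MCM5	201755_at	4.47E-09	mitosis	0
MCM6	201930_at	9.09E-13	mitosis	0
MCM7	208795_s_at	2.14E-05	mitosis	0
MYC	202431_s_at	2.92E-03	mitosis	0
POLD1	203422_at	1.51E-04	mitosis	0
PRIM1	205053_at	9.19E-03	mitosis	0
RFC5	203209_at	5.46E-04	mitosis	0
RRM2	201890_at	1.74E-13	mitosis	0
SNRPD3	202567_at	1.18E-06	mitosis	0
TK1	202338_at	1.14E-11	mitosis	0
TYMS	202589_at	3.61E-09	mitosis	0
UHRF1	225655_at	3.07E-10	mitosis	0
WDHD1	216228_s_at	2.34E-06	mitosis	0
CCDC86	203119_at	1.05E-05	other	0
ELOVL6	204256_at	8.42E-04	other	0
GABRP	205044_at	5.67E-06	other	0
KRT17	205157_s_at	5.87E-03	other	0
MMP12	204580_at	2.68E-05	other	0
NUP107	218768_at	5.26E-04	other	0
NUTF2	202397_at	1.34E-04	other	0
PA2G4	208676_s_at	3.67E-03	other	0
SLC7A5	201195_s_at	5.40E-14	other	0
SQLE	209218_at	1.45E-06	other	0
WASF1	204165_at	6.87E-03	other	0
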