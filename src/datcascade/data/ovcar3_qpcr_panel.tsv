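gene_id	qpcr_log2fc	rnaseq_log2fc
PDLIM3	13.16	5.56
TPH2	11.53	8.04
TRHDE	10.67	7.82
KCNT2	10.47	5.09
GAS1	10.24	5.01
CLDN16	9.33	5.29
PRRX1	9.09	4.31
SESN3	9.07	3.41
GALNT13	8.50	4.78
SYTL2	7.63	4.55
SULF1	7.43	3.78
BCHE	6.50	1.31
ATP11B	6.44	3.24
SLIT2	5.33	2.09
SLC6A15	5.29	5.45
SH2D5	5.19	2.51
VEGFC	4.85	4.84
CFL2	4.42	1.98
ARRDC3	4.17	2.24
CRABP2	3.43	1.62
NUDT11	3.34	2.13
EYA4	2.74	0.58
SACS	2.55	1.03
KIF1A	2.36	1.43
ARHGAP28	2.19	1.24
EMP1	2.11	1.20
DDAH1	2.09	0.96
CASC10	2.06	0.50
LRRC17	-0.94	-1.42
LRG1	-0.97	-2.72
TMCC3	-1.03	-2.25
SPRY4	-1.67	-1.91
F2R	-2.09	-3.80
SULT1A1	-2.67	-3.43
PBX1	-2.78	-2.29
SLC7A2	-2.85	-5.47
MXRA8	-3.16	-4.14
NID1	-3.36	-4.50
RUNX1	-3.59	-1.64
PROCR	-4.28	-5.77
LIPG	-5.20	-5.68
PDE1A	-5.76	-7.53
PTPRD	-6.38	-7.88
VCAN	-6.60	-5.64
THBS1	-9.79	-4.06
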