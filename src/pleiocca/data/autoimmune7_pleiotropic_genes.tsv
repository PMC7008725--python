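gene	chrom	n_snps	r	metacca_p	p_CEL	p_IBD	p_MS	p_PBC	p_RA	p_SLE	p_T1D	gene_type
ADAD1	4	3	0.08	1.05E-30	1.00E-06	1.00E-06	0.29	1.23E-02	1.10E-05	2.58E-02	6.97E-03	confirmed
ADCY5	3	11	0.05	1.44E-06	2.40E-02	3.91E-02	1.00E-06	3.75E-02	1.29E-02	1.32E-02	0.87	novel
AHI1	6	13	0.12	2.03E-87	5.05E-02	0.30	1.00E-06	0.36	0.54	1.94E-03	4.75E-02	confirmed
ATG5	6	19	0.05	1.53E-16	0.33	7.00E-06	0.53	1.87E-03	1.54E-03	1.00E-06	0.94	confirmed
C1orf106	1	14	0.08	1.82E-33	0.09	3.09E-02	7.79E-02	1.22E-02	1.00E-06	5.30E-05	3.73E-02	confirmed
C1orf141	1	1	0.05	7.70E-11	0.44	1.00E-06	0.87	1.00E-06	9.85E-03	2.93E-03	0.53	novel
C5orf56	5	12	0.06	1.87E-16	2.07E-03	1.00E-06	0.29	0.67	9.41E-02	1.86E-02	6.48E-02	novel
CALU	7	6	0.05	2.10E-10	0.20	1.75E-02	2.21E-02	1.00E-06	1.00E-06	1.00E-06	7.18E-02	novel
CCDC136	7	2	0.08	3.51E-25	0.030	2.90E-02	0.38	1.00E-06	1.00E-05	1.00E-06	0.39	novel
CD58	1	8	0.05	5.43E-13	0.520	2.44E-02	0.158	0.71	1.00E-06	0.60	6.64E-02	confirmed
CIITA	16	8	0.07	4.85E-28	4.05E-03	0.21	1.00E-06	1.00E-06	0.54	1.47E-04	1.00E-06	confirmed
CLEC16A	16	47	0.10	9.26E-85	1.28E-02	2.12E-03	1.00E-06	1.00E-06	0.62	1.00E-06	1.00E-06	confirmed
CUL2	10	9	0.06	2.56E-19	0.40	1.00E-06	0.39	2.91E-02	0.78	4.12E-04	5.76E-02	novel
CUX2	12	42	0.08	2.28E-34	0.45	7.00E-06	0.119	2.60E-03	3.06E-02	0.12	1.00E-06	novel
DEAF1	11	9	0.05	7.99E-14	0.40	9.22E-02	0.85	9.31E-02	0.86	1.00E-06	0.42	novel
DGKQ	4	1	0.05	1.61E-15	0.88	0.43	2.18E-03	1.00E-06	9.95E-02	4.57E-03	0.32	novel
DNMT1	19	10	0.04	6.97E-07	0.39	6.87E-04	7.82E-04	2.00E-06	5.03E-04	1.00E-06	9.33E-02	novel
EFR3B	2	11	0.13	1.70E-99	0.34	1.00E-06	2.72E-02	1.00E-06	2.78E-03	0.47	1.54E-02	novel
ERAP2	5	11	0.09	1.77E-49	0.98	1.00E-06	0.25	6.88E-04	0.45	0.57	4.76E-02	confirmed
EVI5	1	15	0.06	4.08E-19	0.39	0.23	1.00E-06	0.65	1.18E-02	0.23	1.50E-02	novel
FGF2	4	13	0.06	1.78E-08	1.00E-06	1.00E-06	9.08E-03	0.39	3.04E-03	0.18	1.40E-05	novel
FYCO1	3	6	0.05	2.73E-11	1.00E-06	2.45E-02	1.00E-02	0.74	0.49	0.57	0.86	novel
GRIP1	12	67	0.12	2.20E-62	1.39E-02	1.00E-06	0.20	0.25	0.25	4.43E-02	0.73	novel
HNF1B	17	4	0.06	2.17E-10	0.14	5.60E-03	0.44	0.11	2.94E-02	0.31	1.00E-06	novel
IKZF1	7	17	0.05	4.37E-10	0.02	0.42	7.70E-02	0.29	4.02E-04	0.49	1.00E-06	confirmed
IKZF3	17	2	0.18	2.57E-203	0.41	1.00E-06	9.31E-02	0.47	0.43	0.54	2.63E-02	confirmed
IL22RA2	6	3	0.04	1.55E-11	0.19	0.46	1.00E-06	2.85E-03	0.67	3.28E-02	0.12	novel
IL23R	1	9	0.23	1.00E-232	0.90	1.00E-06	0.45	1.00E-06	0.11	8.16E-02	0.91	confirmed
INPP1	2	1	0.04	3.40E-06	0.35	0.25	0.695	4.30E-05	3.65E-03	1.00E-06	0.56	novel
IRF1	5	1	0.11	6.56E-72	9.87E-03	1.00E-06	4.58E-02	0.42	3.38E-02	0.53	5.98E-02	confirmed
ITGAM	16	8	0.09	2.41E-48	5.22E-02	0.80	7.03E-02	0.17	0.20	1.00E-06	0.23	novel
JAK2	9	11	0.14	6.34E-118	0.18	1.00E-06	2.21E-03	0.63	0.40	8.33E-02	0.53	confirmed
KIAA1109	4	24	0.05	5.27E-16	2.00E-06	1.00E-05	1.79E-03	0.12	4.27E-02	0.35	1.00E-06	confirmed
LINC00271	6	9	0.04	1.22E-08	1.63E-02	0.97	1.00E-06	0.48	0.26	1.16E-03	1.78E-03	novel
LOC101927051	22	8	0.05	5.60E-11	0.55	1.00E-06	0.13	1.00E-06	3.00E-06	4.24E-04	4.84E-03	novel
LOC285626	5	2	0.12	3.83E-97	0.50	1.00E-06	5.05E-02	0.40	0.74	0.94	0.51	novel
LTF	3	5	0.04	5.48E-09	1.00E-06	0.17	0.33	0.76	5.55E-02	0.93	1.51E-04	novel
MACROD2	20	15	0.04	9.46E-07	0.35	4.60E-05	2.91E-02	1.00E-06	6.85E-03	0.12	1.88E-02	novel
MAGI3	1	18	0.06	7.55E-24	0.65	1.10E-02	0.27	0.81	1.00E-06	8.90E-05	1.00E-06	confirmed
MAP3K7	6	2	0.11	2.77E-66	0.30	1.00E-06	0.31	7.85E-02	0.25	0.48	0.46	confirmed
MAP4K4	2	32	0.07	3.30E-24	1.00E-06	1.00E-06	0.15	5.08E-02	0.73	9.30E-03	7.47E-02	novel
MPZL3	11	2	0.04	5.37E-09	1.45E-02	0.86	6.22E-04	1.00E-06	1.00E-06	1.45E-03	0.18	novel
MST1R	3	1	0.08	3.72E-37	0.93	1.00E-06	0.56	0.4588	0.84	1.27E-02	5.08E-02	confirmed
NSD1	5	9	0.07	1.16E-25	0.55	1.00E-06	1.00E-05	0.16	1.42E-02	0.55	1.44E-02	novel
PAPOLG	2	5	0.04	7.00E-08	4.00E-06	1.00E-06	1.07E-02	0.11	1.00E-06	4.40E-02	0.50	novel
PLCL2	3	23	0.05	2.97E-17	0.18	0.22	1.50E-02	3.00E-06	1.00E-06	0.62	0.72	confirmed
PRKAA1	5	3	0.06	4.54E-18	0.12	1.00E-06	3.90E-02	0.371	0.34	0.12	0.30	novel
PTPN2	18	11	0.05	1.06E-09	6.00E-06	1.00E-06	7.66E-03	9.56E-02	1.00E-06	0.15	1.00E-06	confirmed
PUS10	2	10	0.13	5.93E-101	7.00E-06	1.00E-06	1.60E-02	0.40	0.20	0.16	7.89E-02	confirmed
RBM17	10	5	0.06	2.49E-25	0.252	3.36E-02	3.10E-05	0.64	1.00E-06	0.47	1.00E-06	novel
RNASET2	6	2	0.04	1.22E-08	0.162	1.00E-06	0.99	4.08E-04	1.77E-02	8.93E-02	0.24	confirmed
SH3BP1	22	8	0.05	5.60E-11	0.562	1.00E-06	0.11	1.00E-06	3.00E-06	4.39E-04	4.35E-03	novel
SHISA5	3	2	0.14	5.12E-118	3.68E-02	1.00E-06	0.32	0.70	0.60	0.46	0.14	novel
SLC26A4	7	2	0.08	1.29E-35	0.90	1.00E-06	2.79E-02	0.17	0.90	0.23	9.07E-02	novel
THADA	2	50	0.15	9.70E-149	0.48	1.00E-06	0.30	0.51	0.83	4.70E-02	2.17E-03	confirmed
TNFAIP3	6	2	0.08	6.86E-33	0.48	0.38	1.99E-04	2.60E-03	9.00E-06	1.00E-06	5.88E-02	confirmed
TNIK	3	44	0.11	3.66E-54	1.00E-06	0.198	5.73E-04	8.17E-02	0.34	2.71E-03	8.36E-02	novel
TNIP1	5	23	0.07	3.52E-34	0.12	0.158	0.49	4.82E-04	9.01E-04	1.00E-06	0.39	confirmed
TNS1	2	11	0.07	1.56E-18	0.11	1.00E-06	0.64	3.03E-02	8.87E-02	0.88	2.76E-02	novel
TP63	3	31	0.07	1.05E-26	1.00E-06	2.00E-06	2.85E-02	0.33	0.68	0.25	7.99E-02	novel
TRPV4	12	11	0.04	2.37E-09	3.43E-04	3.74E-02	0.15	1.46E-03	1.13E-03	0.25	1.00E-06	confirmed
TTC34	1	2	0.04	1.98E-09	5.60E-05	1.19E-02	1.00E-06	4.60E-05	1.30E-04	4.65E-02	0.46	confirmed
TYK2	19	5	0.04	1.06E-06	0.11	1.00E-06	3.00E-06	2.80E-05	5.00E-06	7.00E-06	3.82E-03	confirmed
USP34	2	11	0.18	9.72E-217	4.00E-06	1.00E-06	4.59E-02	0.38	1.15E-02	0.40	0.35	novel
WDR78	1	13	0.10	4.90E-52	2.04E-03	1.00E-06	0.12	8.53E-03	1.30E-02	0.85	0.76	novel
WNT11	11	3	0.06	4.60E-19	0.19	1.00E-06	0.83	0.19	0.33	0.47	0.45	novel
ZNF365	10	39	0.17	1.41E-164	0.25	1.00E-06	0.16	0.55	0.12	4.37E-02	0.36	novel
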