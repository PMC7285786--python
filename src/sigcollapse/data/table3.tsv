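signature	gene	log2FC_discovery	p_discovery	log2FC_GSE62646	p_GSE62646	log2FC_GSE59867	p_GSE59867
ADAP2	ADAP2	0.64	8.70E-05	0.62	6.40E-08	0.42	4.54E-13
KLRB1	KLRB1	-0.64	3.82E-05	-0.57	1.27E-03	-0.44	2.85E-06
KLRB1	KLRC1	-0.69	1.09E-02	-0.80	3.60E-05	-0.70	5.28E-10
KLRB1	KLRD1	-0.77	3.78E-04	-0.69	1.64E-04	-0.70	7.77E-13
KLRB1	KLRF1	-0.65	1.90E-03	-0.79	1.06E-03	-0.70	1.20E-08
MIR21	MIR21	1.51	5.45E-03	0.36	3.57E-02	0.80	2.03E-12
MIR21	BCL6	0.80	3.38E-03	0.51	1.06E-04	0.48	2.37E-12
MIR21	CCR1	0.55	1.97E-02	0.57	1.63E-04	0.67	1.29E-13
MIR21	PDGFD	-0.52	1.29E-04	-0.68	1.56E-04	-0.65	3.06E-12
MIR21	SGK1	0.54	3.91E-02	0.18	3.00E-01	0.34	4.78E-04
MIR21	TGFBR3	-0.56	7.32E-03	-0.59	1.06E-03	-0.58	4.65E-11
MIR21	FPR1	0.66	6.74E-03	0.28	5.20E-02	0.52	7.58E-12
MIR21	S100A12	0.70	4.78E-03	0.43	4.71E-03	0.55	1.07E-10
MIR223	MIR223	0.63	9.43E-03	0.61	6.85E-05	0.53	4.85E-09
MIR223	MAFB	0.65	2.16E-02	0.45	5.70E-04	0.52	7.80E-12
NeutrophilDegranulation	BST1	0.54	5.13E-03	0.12	2.70E-01	0.50	9.74E-15
NeutrophilDegranulation	C3AR1	0.60	1.88E-02	0.34	3.14E-02	0.48	1.07E-06
NeutrophilDegranulation	CD14	0.57	5.09E-03	0.48	3.67E-05	0.60	5.79E-18
NeutrophilDegranulation	CLEC4D	0.81	3.75E-02	-0.29	6.48E-02	0.22	1.72E-02
NeutrophilDegranulation	CR1	0.58	3.57E-02	0.62	9.67E-04	0.64	1.51E-13
NeutrophilDegranulation	FPR1	0.66	6.74E-03	0.28	5.20E-02	0.52	7.58E-12
NeutrophilDegranulation	FPR2	0.65	4.06E-02	0.34	6.67E-02	0.63	6.28E-10
NeutrophilDegranulation	S100A12	0.70	4.78E-03	0.43	4.71E-03	0.55	1.07E-10
NeutrophilDegranulation	SLC11A1	0.59	2.38E-04	0.54	6.12E-05	0.50	2.58E-12
NeutrophilDegranulation	TLR2	0.70	5.09E-03	0.06	5.93E-01	0.22	3.57E-04
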