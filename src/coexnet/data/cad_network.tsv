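gene_a	gene_b	pcc	mr	edge_type	rank_product
Sobic.004G273800	Sobic.004G071000	0.74	20.49	coexp_pos	420
Sobic.001G316400	Sobic.004G071000	0.74	9.38	coexp_pos	88
Sobic.002G260000	Sobic.004G071000	0.77	6.928	coexp_pos	48
Sobic.007G115100	Sobic.004G071000	0.82	4.898	coexp_pos	24
Sobic.003G225300	Sobic.004G071000	0.81	4.898	coexp_pos	24
Sobic.005G180700	Sobic.004G071000	0.77	20.39	coexp_pos	416
Sobic.003G244100	Sobic.004G071000	0.73	12.72	coexp_pos	162
Sobic.003G343900	Sobic.004G071000	0.74	19.74	coexp_pos	390
Sobic.004G145200	Sobic.004G071000	0.75	19.49	coexp_pos	380
Sobic.004G071000	Sobic.004G220300	0.83	4.898	coexp_pos	24
Sobic.004G071000	Sobic.001G317300	0.69	28.61	coexp_pos	819
Sobic.004G071000	Sobic.001G483600	0.79	4.898	coexp_pos	24
Sobic.004G071000	Sobic.010G052200	0.79	22.44	coexp_pos	504
Sobic.004G071000	Sobic.009G033600	0.77	27.14	coexp_pos	737
Sobic.004G071000	Sobic.010G192400	0.7	28.46	coexp_pos	810
Sobic.004G071000	Sobic.007G047300	0.84	3.162	coexp_pos	10
Sobic.004G071000	Sobic.010G209600	0.77	13.49	coexp_pos	182
Sobic.004G071000	Sobic.009G027200	0.67	15.87	coexp_pos	252
Sobic.004G071000	Sobic.007G179900	0.8	7.071	coexp_pos	50
Sobic.004G071000	Sobic.008G008900	0.73	28.98	coexp_pos	840
Sobic.004G071000	Sobic.006G082000	0.73	12.04	coexp_pos	145
Sobic.004G071000	Sobic.004G212300	0.78	17.6	coexp_pos	310
Sobic.004G071000	Sobic.001G052900	0.8	2.449	coexp_pos	6
Sobic.004G071000	Sobic.004G232900	0.79	3.0	coexp_pos	9
Sobic.004G071000	Sobic.010G030700	0.77	5.656	coexp_pos	32
Sobic.004G273800	Sobic.001G316400	0.72	17.54	coexp_pos	308
Sobic.004G273800	Sobic.003G225300	0.76	18.33	coexp_pos	336
Sobic.004G273800	Sobic.003G343900	0.73	21.63	coexp_pos	468
Sobic.004G273800	Sobic.004G220300	0.75	24.49	coexp_pos	600
Sobic.004G273800	Sobic.001G483600	0.8	2.828	coexp_pos	8
Sobic.004G273800	Sobic.010G209600	0.75	14.96	coexp_pos	224
Sobic.004G273800	Sobic.007G179900	0.84	1.0	coexp_pos	1
Sobic.004G273800	Sobic.004G232900	0.74	9.165	coexp_pos	84
Sobic.001G316400	Sobic.003G225300	0.74	8.0	coexp_pos	64
Sobic.001G316400	Sobic.004G220300	0.77	5.196	coexp_pos	27
Sobic.001G316400	Sobic.001G483600	0.71	22.97	coexp_pos	528
Sobic.001G316400	Sobic.007G047300	0.74	16.88	coexp_pos	285
Sobic.001G316400	Sobic.004G212300	0.73	22.8	coexp_pos	520
Sobic.001G316400	Sobic.004G232900	0.69	27.92	coexp_pos	780
Sobic.002G260000	Sobic.003G244100	0.7	12.84	coexp_pos	165
Sobic.002G260000	Sobic.004G145200	0.78	4.242	coexp_pos	18
Sobic.002G260000	Sobic.001G483600	0.74	8.124	coexp_pos	66
Sobic.002G260000	Sobic.010G192400	0.81	1.0	coexp_pos	1
Sobic.002G260000	Sobic.009G027200	0.64	25.9	coexp_pos	671
Sobic.002G260000	Sobic.004G232900	0.72	8.366	coexp_pos	70
Sobic.002G260000	Sobic.010G030700	0.72	11.48	coexp_pos	132
Sobic.007G115100	Sobic.003G225300	0.77	29.34	coexp_pos	861
Sobic.007G115100	Sobic.003G244100	0.73	20.97	coexp_pos	440
Sobic.007G115100	Sobic.010G052200	0.81	22.58	coexp_pos	510
Sobic.007G115100	Sobic.009G033600	0.79	28.58	coexp_pos	817
Sobic.007G115100	Sobic.007G047300	0.81	15.71	coexp_pos	247
Sobic.007G115100	Sobic.007G179900	0.81	9.899	coexp_pos	98
Sobic.007G115100	Sobic.001G052900	0.76	18.43	coexp_pos	340
Sobic.003G225300	Sobic.005G180700	0.84	1.414	coexp_pos	2
Sobic.003G225300	Sobic.003G343900	0.78	10.9	coexp_pos	119
Sobic.003G225300	Sobic.004G220300	0.79	15.49	coexp_pos	240
Sobic.003G225300	Sobic.001G483600	0.82	2.236	coexp_pos	5
Sobic.003G225300	Sobic.007G047300	0.83	6.0	coexp_pos	36
Sobic.003G225300	Sobic.010G209600	0.8	6.928	coexp_pos	48
Sobic.003G225300	Sobic.004G212300	0.78	22.64	coexp_pos	513
Sobic.003G225300	Sobic.010G030700	0.77	5.0	coexp_pos	25
Sobic.005G180700	Sobic.003G244100	0.72	23.83	coexp_pos	568
Sobic.005G180700	Sobic.004G220300	0.82	8.366	coexp_pos	70
Sobic.005G180700	Sobic.007G047300	0.79	23.66	coexp_pos	560
Sobic.005G180700	Sobic.010G209600	0.84	2.449	coexp_pos	6
Sobic.003G244100	Sobic.007G047300	0.75	13.26	coexp_pos	176
Sobic.003G244100	Sobic.004G212300	0.72	27.0	coexp_pos	729
Sobic.003G244100	Sobic.010G030700	0.69	17.97	coexp_pos	323
Sobic.003G343900	Sobic.004G145200	0.73	26.26	coexp_pos	690
Sobic.003G343900	Sobic.001G483600	0.77	8.366	coexp_pos	70
Sobic.003G343900	Sobic.007G047300	0.83	3.741	coexp_pos	14
Sobic.003G343900	Sobic.004G212300	0.76	22.24	coexp_pos	495
Sobic.004G145200	Sobic.010G192400	0.76	8.062	coexp_pos	65
Sobic.004G145200	Sobic.007G047300	0.81	6.782	coexp_pos	46
Sobic.004G145200	Sobic.008G008900	0.73	29.98	coexp_pos	899
Sobic.004G220300	Sobic.010G052200	0.87	4.0	coexp_pos	16
Sobic.004G220300	Sobic.007G047300	0.84	7.416	coexp_pos	55
Sobic.004G220300	Sobic.007G179900	0.82	6.708	coexp_pos	45
Sobic.004G220300	Sobic.004G212300	0.85	4.898	coexp_pos	24
Sobic.004G220300	Sobic.004G232900	0.71	27.92	coexp_pos	780
Sobic.001G317300	Sobic.006G082000	0.67	29.98	coexp_pos	899
Sobic.001G317300	Sobic.010G030700	0.69	15.87	coexp_pos	252
Sobic.001G483600	Sobic.010G209600	0.77	9.165	coexp_pos	84
Sobic.001G483600	Sobic.004G232900	0.75	4.898	coexp_pos	24
Sobic.001G483600	Sobic.010G030700	0.75	7.937	coexp_pos	63
Sobic.010G052200	Sobic.009G033600	0.89	4.0	coexp_pos	16
Sobic.010G052200	Sobic.007G047300	0.91	2.828	coexp_pos	8
Sobic.010G052200	Sobic.004G212300	0.85	10.0	coexp_pos	100
Sobic.009G033600	Sobic.007G047300	0.91	1.732	coexp_pos	3
Sobic.009G033600	Sobic.004G212300	0.8	21.02	coexp_pos	442
Sobic.010G192400	Sobic.009G027200	0.66	14.56	coexp_pos	212
Sobic.010G192400	Sobic.010G030700	0.75	6.708	coexp_pos	45
Sobic.007G047300	Sobic.004G212300	0.92	1.0	coexp_pos	1
Sobic.010G209600	Sobic.010G030700	0.75	10.95	coexp_pos	120
Sobic.009G027200	Sobic.001G052900	0.73	3.741	coexp_pos	14
Sobic.007G179900	Sobic.004G232900	0.73	18.33	coexp_pos	336
Sobic.008G008900	Sobic.006G082000	0.74	8.66	coexp_pos	75
Sobic.006G082000	Sobic.001G052900	0.74	6.633	coexp_pos	44
Sobic.007G207400	Sobic.004G071000	-0.65	23.36	coexp_neg	546
Sobic.004G317300	Sobic.004G071000	-0.71	7.0	coexp_neg	49
Sobic.002G031000	Sobic.004G071000	-0.74	9.591	coexp_neg	92
Sobic.003G426700	Sobic.004G071000	-0.74	21.09	coexp_neg	445
Sobic.004G071000	Sobic.005G005500	-0.73	24.49	coexp_neg	600
Sobic.004G071000	Sobic.009G254500	-0.73	10.58	coexp_neg	112
Sobic.004G071000	Sobic.001G035800	-0.77	14.49	coexp_neg	210
Sobic.004G071000	Sobic.009G191900	-0.72	29.25	coexp_neg	856
Sobic.004G071000	Sobic.004G041500	-0.64	9.433	coexp_neg	89
Sobic.004G071000	Sobic.007G142200	-0.71	14.69	coexp_neg	216
Sobic.004G071000	Sobic.010G128200	-0.75	18.41	coexp_neg	339
Sobic.004G071000	Sobic.010G202700	-0.7	9.165	coexp_neg	84
Sobic.004G071000	Sobic.010G190700	-0.79	10.29	coexp_neg	106
Sobic.004G071000	Sobic.009G127500	-0.7	14.14	coexp_neg	200
Sobic.004G071000	Sobic.010G232100			ppi_pred	
Sobic.004G071000	Sobic.003G403700			ppi_pred	
Sobic.004G071000	Sobic.004G049900			ppi_pred	
Sobic.004G071000	Sobic.004G050000			ppi_pred	
Sobic.004G071000	Sobic.004G050100			ppi_pred	
Sobic.004G071000	Sobic.010G239500			ppi_pred	
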