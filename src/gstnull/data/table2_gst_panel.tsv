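sample_id	GSTM1_copy	GSTM1_expr_x1000	GSTM2_copy	GSTM2_expr_x1000	GSTT1_copy	GSTT1_expr_x1000	GSTT4_copy	GSTT4_expr_x1000
RF1	0	0.00	1	3.99	0	3.13	1	0.00
RM1	0	0.00	1	5.70	1	4.75	1	0.00
RM2	0	0.00	1	5.30	2	110.49	2	0.00
RM4	0	0.00	1	4.27	0	1.98	1	0.00
PF1	1	35.46	2	15.21	0	3.71	1	0.00
PF2	1	3.11	1	5.72	1	69.06	2	0.00
PF3	0	0.00	1	2.73	0	2.79	1	0.00
PF4	0	0.00	1	7.65	1	42.31	1	0.00
PF5	1	26.37	1	7.05	1	50.56	1	0.00
PF6	0	0.00	2	7.08	1	19.90	2	0.00
PF7	0	0.00	1	3.95	2	154.33	2	0.00
PM1	1	58.39	2	8.16	1	52.38	2	0.00
PM2	1	1.97	2	10.89	1	6.03	2	0.00
PM3	1	34.21	1	6.43	1	44.54	1	0.00
PM4	1	26.62	1	6.80	0	2.23	2	0.00
PM5	0	0.00	1	6.59	0	0.86	1	0.00
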