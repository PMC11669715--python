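sample_id	patient_id	group	sex	age_years	who_grade	histology	ki67_text	rin	mutated_genes	chr22_loss	chr1p_loss
RF1	M-105	recurrent	F	69	1	Choroid	1	9.1	NF2,SMARCAL1	Loss of chr 22	Loss of 1p36.33p21.3 (including ARID1A)
RM1	M-020	recurrent	M	24	1	Atypical	3	8.2	NF2,FGFR3	Loss of chr 22	Loss of 1p36.33p11.2, partial loss of 1q21.1q44
RM2	M-077	recurrent	M	76	3	Atypical	3	9.7	NF2,TERT,PTCH1,ARID1A,LRP1B,TET1,YAP1	Loss 22q11.1q13.2	Loss of 1p36.33p11.2 (including ARID1A)
RM4	M-112	recurrent	M	47	2	Choroid	3	9.2	NF2	Loss of ch r22	Loss of 1p36.33p13.3 (including ARID1A)
PF1	M-015	primary	F	57	1	Meningiothelial	2	9.8	NF2,COL6A3	Loss of chr 22	Multiple gains and losses on chr1 (including loss of ARID1A)
PF2	M-064	primary	F	61	1	Fibroblastic	<1	9.7	NF2,CHEK2,SMARCB1,ARID2,MSH3	Loss of ch 22	Loss of 1p36.33p22.1 (including ARID1A)
PF3	M-071	primary	F	63	2	Meningiothelial	<10	5.1	NF2,CHEK2,NF1,KMT2B,KMT2D,PTCH2	Loss of ch 22	Loss of 1p36.33p12
PF4	M-073	primary	F	46	1	Fibrous	2	9.8	NF2,GL12,KDM5C,PARP1	Loss of most of ch 22	Loss of most of 1p, loss of 8p23.3q12.3
PF5	M-089	primary	F	86	2	Meningiothelial	10	9.2	NF2,EGFR,POLE	Loss of chr 22	Loss of 1p36.33p31.1 (including ARID1A)
PF6	M-097	primary	F	64	1	Meningiothelial	5	8.0	NF2	Loss of chr 22	Loss of 1p36.32p32.2 (including ARID1A)
PF7	M-122	primary	F	60	1	Transitional	1	5.8	NF2,FUBP1,VHL	Loss of 22q12.1q13.33	Loss of 1p36.33p12
PM1	M-037	primary	M	66	1	Meningiothelial	3	9.8	NF2,KLF4,KMT2B	Loss of chr 22	Loss of 1p36.33p21.1 (including ARID1A)
PM2	M-055	primary	M	79	2	Atypical	7	6.4	NF2,TET2	Loss of chr 22	Loss of 1p36.33p31.1 (including ARID1A), loss of 1q23.2q44
PM3	M-074	primary	M	80	2	Atypical	10	9.7	NF2,BCOR,MLH1	Loss of chr 22	Loss of 1p36.33p21.1 (including ARID1A)
PM4	M-092	primary	M	83	1	Transitional	<1	9.1	NF2	Loss of chr 22	Loss of 1p36.33p31.3
PM5	M-098	primary	M	41	2	Atypical	12	8.5	NF2,TET1	Loss of 22q11.21q13.33	Loss of 1p36.33p13.1 (including ARID1A)
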