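case	sex	group	age	bmi	cd34_dose	duration	fbg	pbg	hba1c	gada	insulin_pre	insulin_6mo	insulin_12mo	cpeptide_pre	cpeptide_6mo	cpeptide_12mo
1	F	IF	18	17.2	5.95	2.5	6.2	13.8	7.8	410	0.62	0	0	0.11	1.05	1.57
2	M	IF	17	18.7	10.8	1	9.7	9.9	12.9	41.7	0.91	0	0	0.62	1.26	1.25
3	F	IF	21	17.7	17.17	1.5	6.7	8.9	14	153	0.85	0	0	0.62	1.17	1.07
4	M	IF	25	20	8.96	2	7.3	11.3	8.8	289.1	0.41	0.07	0	0.53	1.12	1.58
6	F	IF	15	17.6	24.95	4	6.1	10.5	7.1	2238	0.43	0	0	0.76	0.96	1
9	F	IF	15	16.4	11.49	1.5	5.7	4.6	11.5	4050	0.72	0	0	0.69	1.23	-
5	M	ID	15	17.9	7.5	2	4.1	12.1	9.2	60.2	0.61	0.11	0.46	0.4	0.23	0.39
7	M	ID	14	20.6	12.3	1.5	6.5	11.1	11.1	49.1	0.57	0.25	0.5	0.39	0.42	0.58
8	M	ID	18	20.6	11.68	2	4.4	9.4	9.2	146.7	0.56	0.48	0.19	0.46	1.44	0.85
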