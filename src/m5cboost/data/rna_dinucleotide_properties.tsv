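index	AA	AC	AG	AU	CA	CC	CG	CU	GA	GC	GG	GU	UA	UC	UG	UU
Roll	7.0	4.8	8.5	7.1	9.9	8.7	12.1	8.5	9.4	6.1	8.7	4.8	10.7	9.4	9.9	7.0
Rise	3.18	3.24	3.30	3.24	3.09	3.32	3.30	3.30	3.38	3.22	3.32	3.24	3.26	3.38	3.09	3.18
Shift	-0.08	0.23	-0.04	0.01	0.11	-0.01	0.30	-0.04	0.07	0.07	-0.01	0.23	-0.02	0.07	0.11	-0.08
Twist	31	32	30	33	31	32	27	30	32	35	32	32	32	32	31	31
Slide	-1.27	-1.43	-1.50	-1.36	-1.46	-1.78	-1.89	-1.50	-1.70	-1.39	-1.78	-1.43	-1.45	-1.70	-1.46	-1.27
Tilt	-0.8	0.8	0.5	1.1	1.0	0.3	-0.1	0.5	1.3	0.0	0.3	0.8	-0.2	1.3	1.0	-0.8
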