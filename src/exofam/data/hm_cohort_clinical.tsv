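family	proband_age	affected_individuals	se_range	se_median	al_range	al_median
85	57	2	-19.50/-23.75	-20.25	29.61/31.72	30.85
89	19	1	-9.75/-10.11	-9.93	27.80/27.90	27.85
90	19	1	-7.75/-8.25	-8.01	28.17/28.35	28.26
91	19	2	-8.50/-16.50	-11.88	27.52/28.67	27.81
92	23	1	-7.75/-8.75	-8.25	26.85/26.87	26.86
93	21	2	-10.00/-11.75	-10.81	24.75/27.22	25.85
94	22	2	-8.00/-9.25	-8.50	27.01/27.53	27.32
95	21	1	-6.75/-7.25	-7.00	26.45/26.75	26.60
96	18	1	-6.75/-7.00	-6.86	26.65/26.71	26.68
97	23	2	-6.25/-14.00	-11.25	26.58/29.86	28.03
99	19	1	-8.75/-9.00	-8.88	27.97/28.18	28.08
100	22	2	-6.00/-7.00	-6.50	24.98/26.27	25.60
101	20	1	-8.50/-8.75	-8.63	27.32/27.37	27.35
102	17	1	-7.50/-7.50	-7.50	27.46/27.50	27.48
103	18	1	-8.00/-8.75	-8.38	26.96/27.28	27.12
104	15	2	-5.75/-10.50	-6.71	26.12/26.91	26.28
105	33	1	-8.25/-9.25	-8.75	27.43/27.63	27.53
106	27	2	-5.50/-11.50	-8.56	26.05/27.33	26.62
107	20	3	-6.50/-13.00	-9.63	25.10/27.33	25.85
109	19	1	-7.25/-8.25	-7.75	27.14/27.75	27.45
110	24	1	-7.75/-9.25	-8.50	26.51/26.79	26.65
111	18	1	-6.00/-6.00	-6.00	26.65/26.76	26.71
112	23	1	-10.00/-10.50	-10.25	27.35/27.36	27.36
113	21	2	-12.75/-14.50	-9.31	26.64/26.91	26.42
114	18	1	-7.75/-9.00	-8.38	26.85/27.16	27.01
115	22	2	-6.00/-9.75	-8.28	26.60/28.55	27.62
116	20	1	-10.00/-10.50	-10.25	27.96/28.17	28.07
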