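gene	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12	S13	S14	S15	S16	S17	S18	S19	S20	S21	S22	S23	S24	S25	S26	S27	S28
IL7R	33.09	31.01	49.75	47.16	35.12	46.06	33.44	52.94	61.96	18.56	27.38	43.68	61.44	24.79	46.79	14.89	31.59	11.41	9.17	18.18	19.15	22.71	18.08	25.04	17.17	19.97	5.41	10.07
TESPA1	1.24	1.81	2.72	2.00	1.82	2.75	1.85	1.58	1.31	1.78	2.34	1.23	2.39	0.85	1.43	0.56	1.89	0.14	0.25	0.76	0.00	0.92	0.00	0.00	0.56	1.58	0.00	0.25
SLAMF1	1.71	1.66	1.86	1.53	1.94	2.05	1.86	2.00	1.87	1.99	1.24	2.00	2.27	1.17	1.48	0.53	1.88	0.64	0.47	1.63	1.17	1.27	0.00	0.00	1.00	1.09	0.17	0.73
KATNAL2	1.16	1.10	0.80	1.10	0.54	1.59	0.53	1.33	1.74	1.49	0.94	1.27	0.89	0.64	0.77	0.22	0.70	0.70	0.35	0.17	0.28	0.64	0.00	0.00	0.72	0.37	0.58	0.23
BFSP2	2.26	4.55	3.80	3.58	3.28	7.70	5.61	3.66	4.81	1.91	2.48	4.17	3.53	1.81	3.81	1.69	3.07	0.93	0.27	1.47	2.03	1.14	1.28	0.00	1.40	2.61	0.69	0.21
SLAMF6	2.30	3.71	4.72	3.62	3.11	3.82	4.35	3.44	6.08	4.47	2.04	5.56	5.27	2.21	5.15	2.14	3.88	0.33	0.72	2.35	2.37	2.87	0.00	1.78	1.13	2.36	0.67	1.30
MCOLN2	2.15	2.12	1.54	2.45	2.06	4.15	0.59	1.89	3.11	3.13	2.20	2.49	4.44	2.12	2.33	1.35	2.00	0.26	0.48	0.97	2.21	0.84	0.50	0.42	0.83	0.95	0.42	0.42
PRKCB	0.69	0.92	0.91	1.25	1.31	1.16	0.37	1.27	2.25	1.04	0.47	1.23	1.19	1.08	2.11	0.48	0.68	0.26	0.26	0.78	0.48	0.56	0.14	0.00	0.65	0.32	0.13	0.86
RDH5	2.77	2.88	4.16	3.64	3.69	2.45	5.33	3.09	11.45	4.73	2.53	5.77	5.09	2.68	3.50	0.01	2.45	0.02	0.01	2.58	0.03	4.77	0.00	0.00	1.84	0.52	0.00	0.01
CACNA1I	0.12	0.44	0.75	0.43	0.55	0.68	0.42	0.58	0.71	0.32	0.00	0.58	0.99	0.22	0.45	0.14	0.07	0.09	0.03	0.19	0.00	0.43	0.44	0.00	0.00	0.23	0.00	0.03
FAM3C	12.91	1.59	9.15	11.56	19.41	3.64	11.79	4.44	11.84	9.69	4.43	18.49	3.51	5.53	22.41	5.16	20.21	26.98	28.42	4.07	29.48	42.83	34.86	37.29	11.78	33.21	25.53	31.85
RASGRP2	7.43	10.49	12.13	8.82	9.39	12.43	8.48	12.29	11.81	9.22	4.61	10.41	14.91	3.99	21.65	4.45	8.13	0.94	3.61	8.81	4.37	10.78	0.00	0.00	4.99	6.11	0.89	1.92
PNMA3	0.82	1.35	1.98	0.98	0.67	0.84	0.25	1.18	1.90	0.48	0.65	0.70	1.27	0.29	1.17	0.35	0.63	0.13	0.11	0.54	0.25	0.39	0.00	0.00	0.38	0.87	0.13	0.21
CD3G	12.32	8.93	12.44	10.73	14.99	13.95	9.65	10.06	6.52	13.96	6.25	13.48	20.85	12.03	14.86	4.68	11.84	2.87	2.96	6.93	8.67	9.90	0.34	9.61	9.85	7.97	1.90	3.81
CD3D	55.87	27.13	40.82	58.87	38.77	73.28	42.79	42.60	20.33	69.71	24.77	48.64	86.30	35.96	64.84	17.99	50.76	7.99	12.86	26.56	41.04	40.76	0.00	0.00	29.82	20.72	3.06	14.31
DENND1C	5.97	4.88	4.82	5.38	6.90	8.00	4.47	4.03	2.94	6.38	5.58	5.53	7.93	4.05	6.45	2.76	5.23	2.59	1.83	2.82	4.21	5.73	0.00	0.00	4.12	5.19	0.22	2.83
CD3E	40.56	42.42	56.30	45.07	63.07	56.70	35.61	39.14	40.75	44.51	22.08	44.56	88.82	35.33	61.43	18.52	48.81	14.52	11.04	19.37	35.77	34.25	16.35	46.24	29.72	29.81	5.68	12.46
AOAH	7.84	2.54	8.64	3.57	9.02	11.51	6.07	7.73	2.87	9.80	6.54	1.85	14.34	8.12	8.93	1.97	5.88	1.87	1.57	4.62	3.22	3.83	0.00	0.00	5.58	4.92	1.69	2.04
TSPAN7	14.92	24.09	11.61	14.69	14.14	11.60	6.33	13.84	20.89	10.25	5.60	12.87	12.43	5.92	26.52	8.01	8.85	4.27	3.15	9.63	3.12	7.19	0.00	5.21	13.40	7.05	5.93	1.91
KLRB1	10.77	26.09	23.84	17.58	18.70	16.56	18.88	22.95	15.47	20.01	16.00	24.41	25.87	19.44	32.76	12.52	13.52	6.09	9.01	12.74	12.86	16.24	28.90	0.00	14.34	9.53	3.59	6.89
LY9	1.25	0.27	0.40	0.24	2.21	2.56	1.03	1.89	0.00	0.00	1.71	0.82	2.42	1.77	2.76	0.00	0.70	0.08	0.00	0.27	0.67	0.00	0.00	0.00	0.57	0.00	0.12	0.00
ZC3H12D	0.32	0.41	0.41	0.35	0.53	0.78	0.43	0.44	0.48	0.65	0.35	0.40	0.45	0.37	0.47	0.31	0.59	0.26	0.16	0.39	0.35	0.34	0.00	0.13	0.30	0.19	0.08	0.15
FYN	10.68	9.05	9.98	8.94	15.26	20.90	11.46	13.68	11.13	9.11	8.95	10.38	16.12	9.10	13.27	4.15	11.56	5.14	6.29	11.16	11.07	9.60	0.00	0.00	7.04	8.89	2.04	4.97
LAT	1.39	2.75	1.73	1.43	2.38	2.09	3.71	2.96	2.52	4.01	1.37	1.83	2.93	1.63	3.34	1.05	1.81	1.19	0.97	1.53	2.16	2.07	1.97	0.33	1.38	1.14	0.23	0.51
NEBL	3.48	1.63	3.90	2.55	3.35	2.50	2.15	2.65	1.78	3.47	2.24	4.16	6.73	1.76	3.11	3.47	5.87	6.01	5.56	6.16	8.67	4.12	12.11	9.66	3.75	5.45	2.67	13.52
HSP90AB1	221.53	353.00	258.65	266.09	307.87	268.80	268.16	201.39	0.02	153.03	395.19	260.95	228.47	165.12	198.69	149.89	276.35	481.85	551.54	378.17	433.15	494.92	481.83	458.89	365.47	487.20	164.87	469.71
RTP5	0.03	0.07	0.03	0.08	0.06	0.14	0.14	0.07	0.09	0.11	0.02	0.01	0.15	0.03	0.05	0.03	0.02	0.00	0.06	0.07	0.00	0.02	0.00	0.00	0.01	0.03	0.00	0.00
RAB39B	0.23	0.19	0.20	0.34	0.15	0.28	0.05	0.26	0.31	0.30	0.16	0.65	0.18	0.20	0.29	0.14	0.22	0.09	0.02	0.10	0.18	0.15	0.00	0.00	0.10	0.03	0.10	0.08
TMEM156	2.94	4.66	3.70	3.58	5.42	5.96	3.42	4.31	0.00	2.49	1.54	5.45	7.60	3.93	6.00	1.73	4.27	2.36	1.83	2.00	1.93	0.45	0.00	0.86	3.51	1.17	0.43	1.67
MCM8	0.21	9.08	2.47	4.87	2.89	3.68	4.92	0.72	7.11	2.36	0.30	5.56	6.33	1.31	4.26	0.00	3.32	1.07	0.00	0.00	3.09	1.34	0.00	0.00	0.37	0.16	0.15	0.00
CTLA4	4.26	5.21	6.41	5.36	9.10	10.90	3.29	5.17	4.14	4.44	4.08	5.06	10.16	4.95	4.81	2.13	8.82	1.69	0.69	2.35	4.03	3.04	0.00	0.00	3.65	2.12	0.53	3.05
CSTB	350.66	213.93	172.57	375.21	241.66	255.96	149.99	214.06	112.22	154.54	275.36	214.92	173.51	185.79	258.47	194.88	393.89	315.94	423.05	484.19	612.07	385.77	554.17	785.62	374.77	469.59	60.51	931.09
PYHIN1	2.96	2.55	4.18	2.25	2.12	7.40	2.59	2.89	4.10	3.27	3.72	3.76	8.26	2.48	6.53	1.87	3.30	0.22	1.06	3.12	1.96	2.79	0.00	0.00	1.63	1.76	0.93	2.41
SLA	17.43	0.54	15.34	17.03	15.80	1.30	11.68	17.86	19.16	12.44	1.19	14.58	20.30	12.12	18.01	12.64	1.55	0.98	0.00	1.51	11.92	1.43	18.16	0.00	0.99	0.00	0.12	0.36
CD63	5.13	4.22	4.27	3.53	6.71	6.23	4.04	3.33	0.00	5.66	0.00	3.55	6.38	4.67	4.76	0.00	5.16	0.00	0.00	0.00	3.95	3.61	0.00	3.70	0.00	0.00	0.65	0.85
SHISAL2A	1.04	0.71	1.41	1.75	2.23	1.67	0.84	0.94	2.31	1.44	0.89	1.59	1.44	0.65	1.37	0.61	1.23	0.40	0.20	0.46	0.78	1.65	0.00	0.00	0.51	1.57	0.11	0.16
PDCD11	1.39	18.32	1.36	1.64	2.37	2.50	15.93	2.39	1.33	1.98	20.23	1.24	3.14	2.08	1.36	12.04	3.00	15.49	15.76	17.59	1.71	25.84	27.87	31.03	16.29	19.35	6.03	19.79
PPP1R16B	2.04	2.34	1.86	1.31	3.84	3.92	1.73	2.47	2.79	2.84	1.76	2.36	3.90	1.82	2.56	1.02	2.73	0.79	1.04	1.56	1.75	1.78	0.00	1.70	2.21	2.06	0.24	0.82
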