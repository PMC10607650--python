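# Published per-row derived statistics for the packaged fungal profiles:
# weighted average melting temperature (WAMT, C, mean ± sd over replicates)
# and degree of unsaturation (DU). du_discrepant = "yes" marks the four rows
# whose published DU cannot be recomputed from the published composition
# (likely unlisted minor acids or transcription issues); they are excluded
# from exact-agreement checks.
organism	condition	wamt_mean	wamt_sd	du	du_discrepant
LR1	co2_10C	7.7	0.2	1.49	no
LR1	control_10C	8.7	0.1	1.44	no
LR1	control_25C	11.5	0.1	1.36	no
WT2	co2_10C	6.4	0.7	1.56	no
WT2	control_10C	7.6	0.5	1.41	no
WT2	control_25C	9.9	0.6	1.39	no
WT5	co2_10C	7.0	0.7	0.94	no
WT5	control_10C	8.4	0.2	0.92	no
WT5	control_25C	10.0	1.0	0.91	no
WR1	co2_10C	8.3	0.3	0.91	no
WR1	control_10C	8.2	0.2	0.91	no
WR1	control_25C	10.4	0.4	0.89	no
WT6	co2_10C	8.7	2.3	1.57	no
WT6	control_10C	17.2	2.0	1.13	no
WT6	control_25C	14.9	0.6	1.30	no
WT7	co2_10C	8.9	0.3	1.37	yes
WT7	control_10C	12.6	1.1	1.22	no
WT7	control_25C	15.2	0.6	1.22	no
HT4	co2_10C	8.2	0.2	1.45	no
HT4	control_10C	14.6	1.6	1.10	no
HT4	control_25C	12.8	0.8	1.19	no
M3	co2_10C	6.4	0.4	1.65	no
M3	control_10C	17.9	1.5	1.14	no
M3	control_25C	19.0	0.3	1.06	no
M12	co2_10C	19.2	0.4	1.70	yes
M12	control_10C	28.7	0.8	1.48	yes
M12	control_25C	22.1	1.7	1.38	yes
IF2SW-F4	co2_10C	4.7	0.2	1.89	no
IF2SW-F4	control_10C	10.0	1.7	1.64	no
IF2SW-F4	control_25C	8.0	1.3	1.63	no
DSM 1075	co2_10C	3.6	1.4	1.97	no
DSM 1075	control_10C	6.8	1.5	1.91	no
DSM 1075	control_25C	7.0	1.6	1.72	no
HR2	co2_10C	2.7	1.8	1.80	no
HR2	control_10C	6.0	0.5	1.74	no
HR2	control_25C	6.8	0.8	1.59	no
LT1	co2_10C	6.8	2.2	1.59	no
LT1	control_10C	15.5	2.0	1.17	no
LT1	control_25C	9.1	2.4	1.47	no
KR3	co2_10C	1.1	1.7	1.96	no
KR3	control_10C	7.7	1.6	1.59	no
KR3	control_25C	14.4	2.1	1.32	no
TS1	co2_10C	5.4	1.1	1.84	no
TS1	control_10C	7.9	0.4	1.76	no
TS1	control_25C	9.4	0.9	1.50	no
TS2	co2_10C	2.6	1.5	1.81	no
TS2	control_10C	4.9	0.6	1.73	no
TS2	control_25C	6.9	1.2	1.58	no
M1	co2_10C	19.2	4.0	1.19	no
M1	control_10C	22.0	2.3	1.00	no
M1	control_25C	20.9	2.8	1.10	no
M2	co2_10C	11.7	1.5	1.49	no
M2	control_10C	18.1	1.0	1.22	no
M2	control_25C	26.1	2.7	0.92	no
M4	co2_10C	8.2	1.7	1.59	no
M4	control_10C	17.5	1.9	1.25	no
M4	control_25C	20.0	1.6	1.08	no
M6	co2_10C	4.1	0.6	1.75	no
M6	control_10C	11.2	0.8	1.49	no
M6	control_25C	16.9	1.8	1.17	no
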