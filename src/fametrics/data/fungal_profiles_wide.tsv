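# Fatty-acid composition (% of total peak area, mean ± sd over n biological
# replicates) of 20 food-spoilage fungal strains (9 yeasts, 11 filamentous fungi)
# grown under 20% CO2 / 80% O2 at 10 C (co2_10C), normal atmosphere at 10 C
# (control_10C) and normal atmosphere at 25 C (control_25C).
# "nd" = not detected in the replicates; "<1" = detected below the 1% reporting
# threshold. R. oryzae M1 carries gamma-linolenic acid (C18:3 cis 6, 9, 12)
# instead of the alpha isomer.
organism	species	condition	n	C14:0	C16:0	C16:1 cis 9	C18:0	C18:1 cis 9	C18:1 cis 11	C18:2 cis 9, 12	C18:3 cis 9, 12, 15	C18:3 cis 6, 9, 12	C18:0 3OH
LR1	Candida zeylanoides	co2_10C	3	nd	10.4±0.5	8.9±1.8	<1	38.7±3.1	nd	24.8±1.9	17.3±2.6	nd	nd
LR1	Candida zeylanoides	control_10C	3	<1	11.5±1.5	8.4±2.1	nd	39.6±3.1	nd	25.8±0.5	14.7±4.0	nd	nd
LR1	Candida zeylanoides	control_25C	3	nd	15.1±0.6	4.5±0.3	nd	41.3±1.7	nd	27.0±0.3	12.0±1.3	nd	nd
WT2	Pichia fermentans	co2_10C	3	nd	11.4±1.6	19.8±1.7	0.5±0.2	22.9±2.1	nd	22.9±1.3	22.4±0.4	nd	nd
WT2	Pichia fermentans	control_10C	3	<1	11.1±0.9	23.1±0.4	1.0±0.1	24.9±1.2	nd	27.1±1.0	12.8±0.5	nd	nd
WT2	Pichia fermentans	control_25C	3	nd	14.8±0.4	15.7±1.6	2.2±0.3	21.4±1.3	nd	35.6±0.2	10.3±0.3	nd	nd
WT5	Stenotrophomyces fumitolerans	co2_10C	3	nd	5.6±0.7	74.2±2.6	<1	16.4±2.0	3.8±0.7	nd	nd	nd	nd
WT5	Stenotrophomyces fumitolerans	control_10C	3	<1	8.3±0.3	74.5±0.8	nd	13.5±0.3	3.8±0.7	nd	nd	nd	nd
WT5	Stenotrophomyces fumitolerans	control_25C	3	nd	9.3±1.5	65.5±3.3	nd	18.2±1.9	7.0±1.0	nd	nd	nd	nd
WR1	Stenotrophomyces fumitolerans	co2_10C	3	nd	8.6±0.5	75.6±0.1	<1	13.1±0.2	2.7±0.3	nd	nd	nd	nd
WR1	Stenotrophomyces fumitolerans	control_10C	3	<1	9.0±0.5	79.7±4.6	nd	9.2±3.5	2.9±0.8	nd	nd	nd	nd
WR1	Stenotrophomyces fumitolerans	control_25C	3	nd	10.5±0.4	66.4±1.2	nd	17.2±1.0	5.9±0.4	nd	nd	nd	nd
WT6	Apiotrichum gracile	co2_10C	3	nd	16.2±1.0	1.4±0.3	2.4±2.8	19.6±1.0	nd	47.2±4.2	14.0±1.7	nd	nd
WT6	Apiotrichum gracile	control_10C	3	<1	19.1±1.8	2.3±0.4	2.3±0.4	47.5±3.0	nd	22.9±3.0	5.9±1.4	nd	nd
WT6	Apiotrichum gracile	control_25C	3	nd	20.8±1.1	0.8±0.3	3.9±1.2	24.0±1.7	nd	46.4±2.8	4.2±3.9	nd	nd
WT7	Candida oleophila	co2_10C	3	nd	12.4±0.5	12.4±1.1	0.3±0.1	35.6±0.4	nd	19.1±0.9	20.1±0.3	nd	nd
WT7	Candida oleophila	control_10C	3	<1	14.3±0.5	15.7±1.0	0.8±0.1	41.9±3.8	nd	16.8±1.3	10.3±2.7	nd	nd
WT7	Candida oleophila	control_25C	3	nd	14.7±0.4	1.8±0.1	3.7±0.3	47.8±0.7	nd	23.7±0.4	8.2±0.8	nd	nd
HT4	Candida sake	co2_10C	3	nd	11.1±0.5	11.5±2.7	0.7±0.3	34.0±8.8	nd	28.7±6.8	14.0±4.5	nd	nd
HT4	Candida sake	control_10C	3	<1	14.3±1.2	14.7±0.1	1.1±0.1	50.5±3.4	nd	13.7±3.1	5.8±1.6	nd	nd
HT4	Candida sake	control_25C	3	nd	12.3±0.7	10.5±0.2	1.5±0.3	48.0±4.6	nd	23.0±3.1	4.7±1.3	nd	nd
M3	Rhodotorula alborubescens	co2_10C	3	nd	10.4±0.5	0.9±0.1	1.9±0.1	28.5±0.8	nd	39.1±1.1	19.2±0.4	nd	nd
M3	Rhodotorula alborubescens	control_10C	3	<1	20.4±1.3	1.4±0.2	2.4±0.5	46.8±2.3	nd	20.9±2.1	8.1±1.4	nd	nd
M3	Rhodotorula alborubescens	control_25C	3	nd	18.1±0.5	0.4±0.1	4.0±0.2	54.3±0.8	nd	17.6±0.6	5.6±0.4	nd	nd
M12	Rhodotorula babjevae	co2_10C	3	1.0±<0.1	13.7±0.3	2.1±0.2	1.4±0.2	25.8±0.9	11.5±0.5	25.6±0.2	18.9±0.3	nd	nd
M12	Rhodotorula babjevae	control_10C	3	1.0±0.2	16.9±0.9	3.2±0.5	1.0±0.4	36.5±2.8	16.1±1.3	15.5±0.8	9.6±2.3	nd	nd
M12	Rhodotorula babjevae	control_25C	3	1.1±0.1	17.7±1.2	1.2±0.1	1.7±0.2	39.0±3.3	8.5±0.5	20.2±2.9	10.3±1.9	nd	nd
IF2SW-F4	Penicillium rubens	co2_10C	3	nd	8.8±0.5	nd	6.5±1.0	11.1±1.7	nd	43.7±3.8	30.0±4.8	nd	nd
IF2SW-F4	Penicillium rubens	control_10C	3	nd	14.9±0.6	<1	7.2±1.4	10.2±1.2	nd	51.0±2.7	16.7±0.6	nd	nd
IF2SW-F4	Penicillium rubens	control_25C	3	nd	16.1±1.1	nd	3.6±0.9	8.7±0.5	nd	60.0±2.7	11.6±1.0	nd	nd
DSM 1075	Penicillium rubens	co2_10C	3	nd	8.9±0.4	nd	6.8±2.9	4.2±2.2	nd	47.3±4.6	32.8±4.5	nd	nd
DSM 1075	Penicillium rubens	control_10C	3	nd	10.6±1.3	<1	10.1±2.9	2.7±0.9	nd	44.5±6.2	33.0±5.6	nd	nd
DSM 1075	Penicillium rubens	control_25C	3	nd	16.0±1.6	nd	4.0±0.6	3.5±0.5	nd	61.5±5.2	15.1±3.2	nd	nd
HR2	Penicillium griseofulvum	co2_10C	3	nd	10.5±1.2	1.6±0.5	2.3±1.1	6.9±1.0	nd	64.2±3.3	14.5±2.3	nd	nd
HR2	Penicillium griseofulvum	control_10C	3	nd	13.0±0.4	1.6±0.3	4.2±0.8	8.0±0.9	nd	55.7±3.3	17.5±2.2	nd	nd
HR2	Penicillium griseofulvum	control_25C	3	nd	14.8±0.9	0.8±0.1	2.9±0.3	8.0±0.4	nd	70.2±2.2	3.4±1.1	nd	nd
LT1	Didymella corylicola	co2_10C	3	nd	14.8±2.3	3.9±0.7	1.5±0.2	12.9±2.2	nd	58.6±2.3	8.4±2.6	nd	nd
LT1	Didymella corylicola	control_10C	3	nd	18.8±1.5	8.1±2.2	3.0±1.0	33.8±3.9	nd	33.8±5.0	2.5±0.5	nd	nd
LT1	Didymella corylicola	control_25C	3	nd	14.4±1.8	1.0±0.6	2.8±0.1	20.7±5.4	nd	57.9±6.5	3.2±1.5	nd	nd
KR3	Neurospora tetraspora	co2_10C	3	nd	10.2±1.8	1.5±1.0	1.5±0.4	5.8±0.6	nd	54.3±2.4	26.8±3.5	nd	nd
KR3	Neurospora tetraspora	control_10C	3	nd	12.1±1.3	3.2±0.8	4.7±1.8	15.5±3.2	nd	53.2±1.6	11.2±1.3	nd	nd
KR3	Neurospora tetraspora	control_25C	3	nd	15.0±1.2	1.5±0.1	8.0±2.8	25.7±3.0	nd	45.0±3.1	4.8±2.2	nd	nd
TS1	Penicillium tardochrysogenum	co2_10C	3	nd	11.0±1.1	<1	4.5±0.4	13.4±1.5	nd	42.5±4.2	28.5±6.5	nd	nd
TS1	Penicillium tardochrysogenum	control_10C	3	nd	13.8±0.9	nd	5.8±0.9	10.7±1.3	nd	44.0±2.6	25.6±3.3	nd	nd
TS1	Penicillium tardochrysogenum	control_25C	3	nd	15.0±0.4	nd	2.5±0.4	23.3±3.0	nd	50.4±6.9	8.8±3.3	nd	nd
TS2	Penicillium griseofulvum	co2_10C	3	nd	10.3±0.8	1.7±0.9	2.5±1.1	6.2±1.4	nd	64.6±4.8	14.7±2.3	nd	nd
TS2	Penicillium griseofulvum	control_10C	3	nd	12.9±0.6	1.6±0.4	2.6±0.8	8.1±0.8	nd	60.8±3.5	14.0±4.2	nd	nd
TS2	Penicillium griseofulvum	control_25C	3	nd	14.6±1.0	0.8±0.1	3.0±0.6	8.6±0.7	nd	70.2±3.0	2.7±0.9	nd	nd
M1	Rhizopus oryzae	co2_10C	3	nd	25.5±4.4	8.0±2.9	2.1±0.3	35.1±4.1	nd	11.6±2.0	nd	17.7±4.8	nd
M1	Rhizopus oryzae	control_10C	3	nd	20.3±0.4	5.0±1.0	6.5±2.5	50.4±1.6	nd	8.8±2.4	nd	9.0±2.0	nd
M1	Rhizopus oryzae	control_25C	3	nd	22.0±3.5	0.9±0.4	6.1±1.1	42.1±1.5	nd	19.4±1.5	nd	9.5±1.4	nd
M2	Cladosporium subuliforme	co2_10C	3	nd	20.6±2.2	<1	2.4±0.4	16.2±0.9	nd	49.9±2.1	10.9±0.8	nd	nd
M2	Cladosporium subuliforme	control_10C	2	nd	22.8±1.6	nd	5.4±2.8	28.2±0.2	nd	37.3±0.1	6.3±0.8	nd	nd
M2	Cladosporium subuliforme	control_25C	3	nd	29.1±2.4	nd	8.4±1.8	33.7±0.8	nd	27.9±4.0	0.9±0.2	nd	nd
M4	Alternaria alstroemeriae	co2_10C	3	nd	14.6±1.5	0.9±<0.1	5.0±1.0	8.3±1.6	nd	63.7±1.3	7.5±2.0	nd	nd
M4	Alternaria alstroemeriae	control_10C	3	nd	24.1±1.3	1.3±<0.1	6.2±1.1	16.9±0.6	nd	47.6±3.2	4.0±0.2	nd	nd
M4	Alternaria alstroemeriae	control_25C	3	nd	22.3±2.2	1.5±0.1	6.2±0.6	33.9±2.3	nd	35.8±0.6	0.3±<0.1	nd	nd
M6	Penicillium glandicola	co2_10C	3	nd	12.0±0.7	2.8±0.3	2.4±0.4	7.7±1.3	nd	61.3±2.0	13.9±2.7	nd	nd
M6	Penicillium glandicola	control_10C	3	nd	12.9±0.6	1.2±0.1	8.3±0.2	17.0±1.7	nd	50.6±0.9	10.0±2.5	nd	nd
M6	Penicillium glandicola	control_25C	3	nd	16.4±1.4	1.4±0.1	6.9±1.4	36.7±2.1	nd	37.3±1.5	1.4±0.5	nd	nd
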