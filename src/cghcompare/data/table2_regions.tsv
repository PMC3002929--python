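chrom_region	start_mb	end_mb	direction	group	peaks_mb
1p	58.05	65.50	gain	BLBC/BRCA1	62.00;61.20
2p-1	23.35	25.95	gain	BLBC/BRCA1	26.45*;27.45*
2p-2	56.80	65.20	gain	BLBC/BRCA1	60.85;63.95
3q-1	151.00	161.10	gain	BLBC/BRCA1	150.85*;154.85
3q-2	175.80	186.40	gain	BLBC/BRCA1	178.55;179.80
6p-1	4.30	29.75	gain	BLBC/BRCA1	10.90;19.20;14.05
6p-2	37.05	58.65	gain	BLBC/BRCA1	42.60;53.85;36.65*
6q-1	90.35	90.75	gain	BLBC/BRCA1	86.50*;91.00*
6q-2	105.20	112.30	gain	BLBC/BRCA1	107.15;107.75
6q-3	115.00	120.40	gain	BLBC/BRCA1	
6q-4	123.55	138.75	gain	BLBC/BRCA1	125.55;135.60
7q-1	132.80	139.40	gain	BLBC/BRCA1	134.40;130.25*
7q-2	155.15	157.65	gain	BLBC/BRCA1	156.95;157.65
8q	127.40	132.95	gain	BLBC/BRCA1	120.95*;121.95*;135.30*
10p-1	1.30	12.45	gain	BLBC/BRCA1	5.10;6.45
10p-2	25.65	30.70	gain	BLBC/BRCA1	24.90*;29.20
12p	0.25	11.60	gain	BLBC/BRCA1	0.25;16.10*
13q	101.25	107.00	gain	BLBC/BRCA1	99.55*;110.35*
19q	36.50	41.75	gain	BLBC/BRCA1	39.15;41.10
3p	53.00	53.25	loss	BLBC/BRCA1	53.85*;62.55*
4p	15.65	27.05	loss	BLBC/BRCA1	18.55;11.00*;26.65
5q-1	50.05	146.95	loss	BLBC/BRCA1	57.70;70.75;89.75;102.30;116.25;133.80;70.05;89.85;108.60;118.55;136.30
5q-2	161.40	171.20	loss	BLBC/BRCA1	161.05*;178.30*;157.30*
10q-1	80.65	95.50	loss	BLBC/BRCA1	83.30;90.15;91.05
10q-2	105.55	111.35	loss	BLBC/BRCA1	109.70;108.60
12q-1	47.70	48.35	loss	BLBC/BRCA1	42.15*
12q-2	54.30	59.25	loss	BLBC/BRCA1	55.25;58.40
14q-1	38.30	44.75	loss	BLBC/BRCA1	40.65;36.35*
14q-2	48.35	92.95	loss	BLBC/BRCA1	57.35;79.90;98.00*;55.20;66.15;81.00;95.05*
15q	35.10	49.65	loss	BLBC/BRCA1	44.40;33.70*;42.85
1q	176.70	215.40	gain	luminal	177.35;202.75
8p	35.95	38.90	gain	luminal	41.50
16p	4.30	27.75	gain	luminal	15.80
6q-1	79.05	87.25	loss	luminal	82.35
6q-2	142.75	149.25	loss	luminal	
6q-3	156.90	157.85	loss	luminal	160.05*
11q	104.45	125.35	loss	luminal	112.30;126.60*
13q	91.70	95.50	loss	luminal	99.10*
16q	45.15	88.50	loss	luminal	52.30;79.40
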