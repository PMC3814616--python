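# PLX4720 kinome competitive-binding panel: percent of kinase remaining bound
# to the immobilized probe (percent of control) at 50, 200, 1000 and 10000 nM
# drug. reported_kd_nM is the vendor-reported averaged pointwise estimate;
# ">10000" marks no measurable displacement up to the top concentration.
kinase_name	gene_symbol	pc_50	pc_200	pc_1000	pc_10000	reported_kd_nM	published_ic50_nM
ASK1	MAP3K5	89	98	97	100	14179.29
ASK2	MAP3K6	94	100	100	100
BLK	BLK	91	78	32	1	446.56
BRAF(V600E)	BRAF	38	19	3.9	0.1	32.04	13
BRK	PTK6	47	14	2.4	0.2	30.38	130
DLK	MAP3K12	95	98	100	92
FGR	FGR	69	38	11	2.5	153.47
HPK1	MAP4K1	100	100	100	47
LZK	MAP3K13	94	100	96	75
MAP3K1	MAP3K1	96	100	92	84
MAP3K15	MAP3K15	94	97	91	59
MAP3K2	MAP3K2	100	93	87	41
MAP3K3	MAP3K3	94	97	98	75
MAP3K4	MAP3K4	100	100	100	65
MAP4K2	MAP4K2	98	100	99	67
MAP4K3	MAP4K3	100	95	90	56
MAP4K4	MAP4K4	92	99	100	46
MAP4K5	MAP4K5	96	100	63	8	1257.42
MEK3	MAP2K3	100	100	100	64
MEK4	MAP2K4	48	27	2.6	0.05	37.96
MEK6	MAP2K6	82	100	100	47
MINK	MINK1	89	100	98	55
MKK7	MAP2K7	100	100	100	84
MLK1	MAP3K9	100	100	100	100	>10000	>5000
MLK2	MAP3K10	100	82	100	76
MLK3	MAP3K11	100	100	100	100
MST1	STK4	100	93	84	55	6709.79	>5000
OSR1	OXSR1	100	94	95	42
PAK1	PAK1	93	97	83	22
RIPK1	RIPK1	99	87	85	50
SRMS	SRMS	1.9	0.55	0.05	0	0.64
STK39	STK39	100	100	100	59
TAK1	MAP3K7	90	88	85	49
TAOK1	TAOK1	87	94	89	65	7532.57	>5000
TAOK2	TAOK2	92	100	93	51
TAOK3	TAOK3	100	98	96	58
TNIK	TNIK	97	89	79	24
ZAK	ZAK	20	4	0.7	0.1	9.47
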