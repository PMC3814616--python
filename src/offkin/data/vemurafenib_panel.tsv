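# Vemurafenib kinome competitive-binding panel: percent of kinase remaining
# bound to the immobilized probe (percent of control) at 50, 200, 1000 and
# 10000 nM drug. reported_kd_nM is the vendor-reported averaged pointwise
# estimate; ">10000" marks no measurable displacement up to the top
# concentration.
kinase_name	gene_symbol	pc_50	pc_200	pc_1000	pc_10000	reported_kd_nM	published_ic50_nM
ASK1	MAP3K5	90	94	97	100	11972.22	>1000
ASK2	MAP3K6	94	98	100	74
BLK	BLK	96	66	30	0.55	518.03	547
BRAF(V600E)	BRAF	63	25	5.4	0.5	64.78	31
BRK	PTK6	63	28	6.9	0.35	68.04	213
DLK	MAP3K12	98	97	66	92
FGR	FGR	65	49	13	1.6	149.26	63
HPK1	MAP4K1	95	88	67	15
LZK	MAP3K13	100	99	93	74
MAP3K1	MAP3K1	98	84	89	81
MAP3K15	MAP3K15	84	100	84	91
MAP3K2	MAP3K2	91	91	89	83
MAP3K3	MAP3K3	87	97	100	94
MAP3K4	MAP3K4	95	92	87	46
MAP4K2	MAP4K2	99	82	95	46
MAP4K3	MAP4K3	80	90	82	24
MAP4K4	MAP4K4	96	92	83	23	2842.34	>1000
MAP4K5	MAP4K5	62	33	4.1	0.1	58.21	51
MEK3	MAP2K3	100	96	98	54
MEK4	MAP2K4	19	4.1	0.2	0.05	6.82
MEK6	MAP2K6	91	97	87	21	4080.69	>1000
MINK	MINK1	100	100	91	66	14761.44	>1000
MKK7	MAP2K7	97	95	94	85
MLK1	MAP3K9	100	93	97	41	13979.88	>1000
MLK2	MAP3K10	92	96	87	78
MLK3	MAP3K11	98	100	100	77
MST1	STK4	99	83	51	12
OSR1	OXSR1	100	100	89	98
PAK1	PAK1	99	98	91	46
RIPK1	RIPK1	92	100	99	73
SRMS	SRMS	24	9.6	0.75	0	11.15	18
STK39	STK39	100	100	97	66
TAK1	MAP3K7	93	88	86	88
TAOK1	TAOK1	91	100	97	79
TAOK2	TAOK2	98	92	95	70	11770.83	>1000
TAOK3	TAOK3	92	98	92	80	15468.75	>1000
TNIK	TNIK	95	94	66	11
ZAK	ZAK	9	1.8	0.25	0.05	4.03
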