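class	category	base_formula	n_radyl	c_min	c_max	db_min	db_max	ethers	sphingoid	tier
PC	glycerophospholipid	C8H16NO8P	2	24	44	0	8	O,P	-	primary
PE	glycerophospholipid	C5H10NO8P	2	24	44	0	8	O,P	-	primary
PA	glycerophospholipid	C3H5O8P	2	24	40	0	6	-	-	primary
PG	glycerophospholipid	C6H11O10P	2	24	40	0	6	-	-	primary
BMP	glycerophospholipid	C6H11O10P	2	24	40	0	6	-	-	primary
LPC	glycerophospholipid	C8H18NO7P	1	12	22	0	4	-	-	primary
LPE	glycerophospholipid	C5H12NO7P	1	12	22	0	4	-	-	primary
LPA	glycerophospholipid	C3H7O7P	1	12	22	0	4	-	-	primary
LPG	glycerophospholipid	C6H13O9P	1	12	22	0	4	-	-	primary
DG	glycerolipid	C3H4O5	2	24	40	0	8	-	-	primary
TG	glycerolipid	C3H2O6	3	36	60	0	10	-	-	primary
Cer	sphingolipid	HNO3	2	26	44	0	3	-	d	primary
SM	sphingolipid	C5H13N2O6P	2	26	44	0	3	-	d	primary
HexCer	sphingolipid	C6H11NO8	2	26	44	0	3	-	d	primary
LacCer	sphingolipid	C12H21NO13	2	26	44	0	3	-	d	primary
SPH	sphingolipid	H3NO2	1	16	20	0	2	-	d	primary
FA	fatty acyl	O2	1	12	24	0	6	-	-	secondary
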