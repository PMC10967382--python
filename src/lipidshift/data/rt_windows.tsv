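class	mode	rt_min	rt_max
PC	*	1.7	2.3
PE	*	2.5	3.1
PA	*	3.3	3.9
PG	*	4.1	4.7
BMP	*	4.9	5.5
LPC	*	5.7	6.3
LPE	*	6.5	7.1
LPA	*	7.3	7.9
LPG	*	8.1	8.7
DG	*	8.9	9.5
TG	*	9.7	10.3
Cer	*	10.5	11.1
SM	*	11.3	11.9
HexCer	*	12.1	12.7
LacCer	*	12.9	13.5
SPH	*	13.7	14.3
FA	*	14.5	15.1
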