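class	mode	standard	amount_nmol	role
BMP	NP	BMP(14:0)2	0.2	class_standard
BMP	RP	BMP(14:0)2	2.5	class_standard
Cer	*	Cer(d18:1/12:0)	0.125	class_standard
Cer	*	Cer(d18:1/25:0)	0.125	auxiliary
DG	*	DG(14:0)2	0.5	class_standard
HexCer	*	GlcCer(d18:1/12:0)	0.125	class_standard
LacCer	*	LacCer(d18:1/12:0)	0.125	class_standard
LPA	*	LPA(14:0)	0.1	class_standard
LPC	*	LPC(14:0)	0.5	class_standard
LPE	*	LPE(14:0)	0.1	class_standard
LPG	*	LPG(14:0)	0.02	class_standard
PA	*	PA(14:0)2	0.5	class_standard
PC	*	PC(14:0)2	2	class_standard
PE	*	PE(14:0)2	0.5	class_standard
PG	*	PG(14:0)2	0.1	class_standard
SM	*	SM(d18:1/12:0)	2.125	class_standard
SPH	*	SPH(d17:1)	0.125	class_standard
SPH	*	SPH(d17:0)	0.125	auxiliary
TG	*	TG(14:0)3	0.5	class_standard
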