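family_id	gene	hgvs_c	hgvs_p	effect	exon	band	control_freq
A	SRPK3	c.1519+1G>A	p.?	Splice-donor site	in 14
A	TTN	c.98810_98811del	p.Lys32937Argfs*5	Frameshift	354	A-band
B	SRPK3	c.735dupC	p.Ser246Leufs*17	Frameshift	7
B	TTN	c.93166C>T	p.Arg31056*	Stop gain	340	A-band	4.0264e-06
C	SRPK3	c.1144+1G>A	p.Asp284_Thr383delinsAla	Splice-donor site	in 10
C	TTN	c.95708G>A	p.Cys31903Tyr	Missense (24.6)	345	A-band
C	TTN	c.19234C>G	p.Pro6412Ala	Missense (20.5)	67	I-band
D	SRPK3	c.387+2_387+3delTG	p.?	Splice site	in 4
D	TTN	c.25480C>T	p.Arg8494*	Stop gain	89	I-band
E	SRPK3	c.475C>T	p.His159Tyr	Splice site	5
E	TTN	c.57168_57169insT	p.Ala19057Cysfs*6	Frameshift	294	A-band
F	SRPK3	c.1301T>A	p.Val434Glu	Missense (24.6)	12
F	TTN	c.39226A>T	p.Lys13076*	Stop gain	205	I-band
G	SRPK3	c.1333G>A	p.Asp445Asn	Missense (25.1)	12
G	TTN	c.101440del	p.Glu33814Asnfs*7	Frameshift	358	M-line
H	SRPK3	c.1289G>A	p.Arg430Gln	Missense (25.7)	12
H	TTN	c.38919del	p.Leu12974Trpfs*104	Frameshift	201	n/a	3.2097e-05
J	SRPK3	c.388-2A>G	p.?	Splice-acceptor site	in 4
J	TTN	c.37017del	p.Lys12339Asnfs*60	Frameshift	178	n/a
K	SRPK3	c.1657C>T	p.Arg553Trp	Missense (29.1)	15		5.5092e-06
K	TTN	c.66699T>G	p.Tyr22233*	Stop gain	317	A-band
L	SRPK3	c.190+2T>C	p.?	Donor splice site	in 2
L	TTN	c.24019C>T	p.Arg8007*	Stop gain	84	I-band
M	SRPK3	c.1213_1218del	p.Lys405_Ile406del	Inframe	11
M	TTN	c.86413_86416delinsATG	p.Asp28805Metfs*6	Frameshift	326	A-band
N	SRPK3	c.260G>A	p.Trp87*	Stop gain	3
N	TTN	c.95008C>T	p.Arg31670*	Stop gain	342	A-band	4.0193e-06
O	SRPK3	c.1070_1073del	p.Phe358Leufs*24	Frameshift	10
O	TTN	c.103420C>T	p.Gln34474*	Stop gain	358	M-line
P	SRPK3	c.749-2A>G	p.?	Splice-acceptor site	in 7
P	TTN	c.104092del	p.Arg34698Glufs*49	Frameshift	358	M-line
Q	SRPK3	c.1363G>A	p.Glu455Lys	Missense (28)	13		5.6169e-06
Q	TTN	c.77610del	p.Thr25871Glnfs*16	Frameshift	326	A-band
R	SRPK3	c.1236delC	p.Asn412Lysfs*24	Frameshift	11
R	TTN	c.89766G>C	p.Lys29922Asn	Missense (22.9)	336	A-band
S	SRPK3	c.774+5G>C	p.?	Splice site	in 8
S	TTN	c.91085_91088del	p.Glu30362Glyfs*28	Frameshift	336	A-band
T	SRPK3	c.804_807del	p.Lys269Argfs*2	Frameshift	9
T	TTN	c.104947C>T	p.Gln34983*	Stop gain	358	M-line
U	SRPK3	c.587T>C	p.Leu196Pro	Missense (23.1)	7
U	TTN	c.24897del	p.Glu8300Asnfs*22	Frameshift	87	I-band
V	SRPK3	c.392G>C	p.Arg131Pro	Missense (25.4)	5
V	SRPK3	c.404C>A	p.Pro135His	Missense (28.7)	5
V	TTN	c.76821C>A	p.Asn25607Lys	Missense (21.3)	327	A-band
V	TTN	c.53938G>C	p.Ala17980Pro	Missense (23)	281	A-band
W	SRPK3	c.749-2A>C	p.?	Splice-acceptor site	in 7
W	TTN	c.106259_106271del	p.Pro35420Leufs*54	Frameshift	359	M-line
X	SRPK3	c.469G>A	p.Gly157Arg	Missense (45)	5
X	TTN	c.24087del	p.Lys8030Asnfs*13	Frameshift	84	I-band
Y	SRPK3	c.1245G>A	p.Trp415*	Stop gain	11
Y	TTN	c.70289T>A	p.Val23430Asp	Missense (23.5)	327	A-band
Z	SRPK3	c.1035dupC	p.Ala346Argfs*37	Frameshift	10
Z	TTN	c.48283C>T	p.Arg16095*	Stop gain	258	A-band	8.3429e-06
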