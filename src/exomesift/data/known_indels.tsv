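gene	transcript	cnomen	pnomen	class	affected_bases
BRCA1	NM_007294.3	c.2475del	p.Asp825Glufs*21	D	1
BRCA1	NM_007294.3	c.3005del	p.Asn1002Thrfs*22	D	1
BRCA1	NM_007294.3	c.4806del	p.Gln1604Asnfs*2	D	1
MLH1	NM_000249.3	c.207+1del	.	D	1
MLH1	NM_000249.3	c.1489del	p.Arg497Glyfs*11	D	1
BRCA2	NM_000059.3	c.3545_3546del	p.Phe1182*	D	2
BRCA2	NM_000059.3	c.6275_6276del	p.Leu2092Profs*7	D	2
BRCA2	NM_000059.3	c.7673_7674del	p.Glu2558Valfs*7	D	2
MSH2	NM_000251.1	c.1226_1227del	p.Gln409Argfs*7	D	2
MLH1	NM_000249.3	c.1744_1746del	p.Leu582del	D	3
MSH2	NM_000251.1	c.1786_1788del	p.Asn596del	D	3
APC	NM_001127510.2	c.1875_1878del	p.Asn627Leufs*2	D	4
BRCA2	NM_000059.3	c.6944_6947del	p.Ile2315Lysfs*12	D	4
FLCN	NM_144997.5	c.890_893del	p.Glu297Alafs*25	D	4
MSH2	NM_000251.1	c.1457_1460del	p.Asn486Thrfs*10	D	4
PTEN	NM_000314.4	c.956_959del	p.Thr319Lysfs*24	D	4
APC	NM_001127510.2	c.3183_3187del	p.Gln1062*	D	5
MSH2	NM_000251.1	c.2502_2508del	p.Asn835Leufs*4	D	7
BRCA2	NM_000059.3	c.8736_8744del	p.Asp2913_Ala2915del	D	9
MLH1	NM_000249.3	c.197_207+20del	p.Thr66Lysfs*9	D	31
BRCA1	NM_007294.3	c.1175_1214del	p.Leu392Glnfs*5	D	40
FLCN	NM_144997.5	c.347dup	p.Leu117Alafs*16	I	1
MSH6	NM_000179.2	c.4001+4_4001+8dup	.	I	5
BRCA2	NM_000059.3	c.7762_7764delinsTT	p.Ile2588Phefs*60	D/I	3
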