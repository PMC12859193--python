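gene	cdna	protein	pubmed_id	population	years_bp
MUTYH	c.1103G>A	p.Gly368Asp	23361220	European	8,675
MUTYH	c.452A>G	p.Tyr151Cys	23361220	European	7,500
BRCA1	c.5503C>T	p.Arg1835*	35377490	Pakistani	3,800
BRCA1	c.3228_3229del	p.Gly1077AlafsTer8	18821011	Italian	3,225
BRCA1	c.4096+1G>A	-	37958491	Italian	3,000
BRCA2	c.9026_9030del	p.Tyr3009SerfsTer7	12655574	Northeast Spanish	2,760
BRCA2	c.156_157insAlu	-	34087993	Portuguese	2,600-2,400
BRCA1	c.3331_3334del	p.Gln1111AsnfsTer5	33087180	Iberia	2,400-1,600
MLH1	c.306+5G>A	-	20858721	Spanish	2,200
MUTYH	c.849+3A>C	-	22865608	Italian	2,075
BRCA1	c.4327C>T	p.Arg1443Ter	15883839	Canadian	2,000
TP53	c.1010G>A	p.Arg337His	26618902	Brazilian	2,000
BRCA2	c.5116_5119del	p.Asn1706LeufsTer5	19949853	Spanish	1904
BRCA1	c.5266dup	p.Gln1756ProfsTer74	21119707	European	1,800
BRCA1	c.676del	p.Cys226ValfsTer8	26852130	Northeastern Italian	1,720
BRCA2	c.3036_3039del	p.Ser1013IlefsTer29	9585613	North American	1,600
MSH2	c.1457_1460del	p.Asn486fs	15042510	Southern Chinese	1,560
BRCA1	c.4035del	p.Glu1346LysfsTer20	23274591	Baltic	1,550
BRCA1	c.3048_3052dup	p.Asn1018MetfsTer8	11781691	Western Swedish	1500
BRCA1	c.68_69del	p.Glu23ValfsTer17	26595274	Ashkenazi Jewish	1,500-750
BRCA1	c.548-?_4185+?del	ex9-12del	25716084	Mexican	1,440
BRCA1	c.815_824dup	p.Thr276Alafs	32025337	Senegal	1,400
BRCA2	c.9310_9311del	p.Lys3104ValfsTer6	19949853	Spanish	1,365
BRCA2	c.5146_5149del	p.Tyr1716LysfsTer8	19949853	Spanish	1,200
BRCA1	c.5309G>T	p.Gly1770Val	35216584	North African	800
BRCA1	c.1380dup	p.Phe461IlefsTer19	18215206	Italian	750
BRCA1	c.3626del	p.Lys1208_Leu1209insTer	11039575	Finnish	720-460
BRCA1	c.1016dup	p.Val340GlyfsTer6	16509964	Norse, Dutch, Italian	600
BRCA1	c.1556del	p.Lys519ArgfsTer13	11720839	Norwegian	600
BRCA2	c.5946del	p.Ser1982ArgfsTer22	9585613	Ashkenazi Jewish	580
MSH6	c.10C>T	p.Gln4Ter	25318681	French Canadian	543
BRCA1	c.697_698del	p.Val233AsnfsTer4	11720840	Norwegian	500
BRCA1	c.2641G>T	p.Glu881Ter	15146556	South African	500
BRCA2	c.771_775del	p.Asn257LysfsTer17	8673089	Icelanders	500
MLH1	c.1865T>A	p.Leu622His	20858721	Spanish	425
BRCA2	c.7480C>T	p.Arg2494Ter	11039581	Finnish	400-200
BRCA1	c.5153-1G>A	p.?	19912264	Spanish	380
BRCA2	c.755_758del	p.Asp252ValfsTer24	9585613	North American/France	360
ATM	c.6115G>A	p.Glu2039Lys	38017116	Arab	325
MSH2	c.-823_1076+5984del	-	14871915	North American	313
BRCA1	c.5212G>A	p.Gly1738Arg	17902052	Greek	275
MSH2	c.2152C>T	p.Gln718Ter	30968502	Portuguese	273
BRCA2	c.5771_5774del	p.Ile1924fs	33643918	Southern African	>250
BRCA2	c.7934del	p.Arg2645Asnfs	33643918	Southern African	>250
BRCA2	c.9118-2A>G	p.?	11039580	Finnish	220-140
BRCA2	c.8327T>G	p.Leu2776Ter	11039580	Finnish	220-140
BRCA1	c.4096+3A>G	p.?	11039576	Finnish	200
BRCA1	c.2685_2686del	p.Pro897LysfsTer5	15010701	Dutch	200
BRCA1	c.4097-2A>G	-	11039575	Finnish	<200
BRCA1	c.1175_1214del	p.Leu392GlnfsTer5	8571953	Unknown	180
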