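id	name	formula	n_primary_amines	n_secondary_amines	backbone	concentration	mass_validated
1	diaminopropane	C3H10N2	2	0	3	8 mM	yes
2	spermidine	C7H19N3	2	1	3,4	8 mM	yes
3	spermine	C10H26N4	2	2	3,4,3	1 mM	no
4	cadaverine	C5H14N2	2	0	5	1 mM	yes
5	putrescine	C4H12N2	2	0	4	2.5 mM	yes
6	norspermidine	C6H17N3	2	1	3,3	10 mM	yes
7	m-xylylenediamine	C8H12N2	2	0		2.5 mM	yes
8	N,N'-bis(2-aminoethyl)-1,3-propanediamine	C7H20N4	2	2	2,3,2	5 mM	no
9	N-benzylethylenediamine	C9H14N2	1	1		2.5 mM	yes
10	4-aminobenzylamine	C7H10N2	2	0		2.5 mM	yes
11	4-(2-aminoethyl)aniline	C8H12N2	2	0		0.5 mM	yes
12	4,4'-oxydianiline	C12H12N2O	2	0		0.05 mM	yes
13	4,4'-diaminodiphenylmethane	C13H14N2	2	0		0.01 mM	no
14	1,5-diaminonaphthalene	C10H10N2	2	0		5 mM	no
15	2,2'-thiobisacetamide	C4H8N2O2S	0	0		0.02 mM	no
16	sulfaguanidine	C7H10N4O2S	1	0		2.5 uM	no
17	p-aminobenzenesulfonamide	C6H8N2O2S	1	0		0.05 uM	no
18	urea	CH4N2O	0	0		5 mM	no
19	N-phenylthiourea	C7H8N2S	0	0		5 mM	no
20	3,3'-diamino-N-methyldipropylamine	C7H19N3	2	0		5 mM	no
21	1,8-diaminooctane	C8H20N2	2	0	8	5 mM	yes
22	dipeptide KR	C12H26N6O3	2	0		0.01 mM	no
23	dipeptide KK	C12H26N4O3	3	0		0.01 mM	no
24	dipeptide KQ	C11H22N4O4	2	0		0.01 mM	no
25	dipeptide QN	C9H16N4O5	1	0		0.01 mM	no
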