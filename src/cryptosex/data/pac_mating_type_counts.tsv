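species	site	country	marker	n_strains	n_mlh	n_mat1_1	n_mat1_2	significance	n_mlh_ia	ia	ia_significance
P. turicensis	Rothwald	Austria	M	24	7	4	3	n.a.
P. turicensis	Etang de la Gruere	Switzerland	M	203	12	9	3	*	12	0.28
P. turicensis	Uetliberg	Switzerland	RFLP	145	17	9	8		17	0.07
P. turicensis	Zurichberg	Switzerland	RFLP	48	13	7	6		13	0.13
P. letzii	Parabock	Switzerland	M	58	11	6	5		11	0.69
P. letzii	Rothwald	Austria	M	46	16	7	9		16	-0.01
P. letzii	Zurichberg	Switzerland	RFLP	52	18	13	5	*	18	0.12
P. europaea	Redwater	Canada	M	19	7	1	6	n.a.
P. europaea	Alaska	USA	M	19	12	7	5		13	0.41
P. europaea	Catherine Creek	USA	M	17	8	5	3	n.a.
P. europaea	Sierra Nevada	USA	M	10	9	7	2	n.a.
P. europaea	Bodmeren	Switzerland	M	28	19	7	12		17	-0.18
P. europaea	Scatle	Switzerland	M	36	31	12	19		25	0.02
P. europaea	Rothwald	Austria	M	86	40	23	17		38	-0.12
P. europaea	Alpes Maritimes	France	M	77	43	24	19		34	0.05
P. europaea	Creux du Van	Switzerland	M	123	51	27	24		43	-0.08
P. europaea	Derberence	Switzerland	M	179	64	28	36		48	-0.05
P. europaea	Runcaglia	Switzerland	M	95	45	22	23		41	0.02
P. europaea	Zurichberg	Switzerland	RFLP	130	46	26	20		46	0.04
P. helvetica	Yuba	USA	M	25	5	3	2	n.a.
P. helvetica	Ala Archa	Kirgistan	M	18	7	7	0	n.a.
P. helvetica	Baikalsee	Russia	M	29	11	4	7		12	0.16
P. helvetica	Mansfield	Canada	M	63	16	4	12	*	16	0.46
P. helvetica	Sierra Nevada	USA	M	47	30	17	13		30	0
P. helvetica	Zurichberg	Switzerland	RFLP	40	15	11	4	*	15	-0.03
P. helvetica	Runcaglia	Switzerland	M	98	36	20	16		36	0.02
P. uotolensis	Alpes Maritimes	France	M	17	6	4	2	n.a.
P. subalpina	Creux du Van	Switzerland	M	13	8	6	2	n.a.
P. subalpina	Etang de la Gruere	Switzerland	M	15	14	8	6		14	0.05
P. subalpina	Massif Central/La Fage	France	M	70	30	14	16		29	-0.08
P. subalpina	Sheep Creek	USA	M	12	7	2	5	n.a.
P. subalpina	Marsh Island	USA	M	23	13	3	10	*	13	0.17
P. subalpina	Pyrenees	France	M	19	13	5	6		13	0.92
P. subalpina	Redwater	Canada	M	12	11	3	8		10	-0.06
P. subalpina	Baikalsee	Russia	M	16	13	10	3	*	12	0.27
P. subalpina	Bialowieza	Poland	M	60	40	10	30	**	40	2.12	***
P. subalpina	Noonday	USA	M	22	15	8	7		14	0.11
P. subalpina	Grass Creek	USA	M	28	22	11	11		21	-0.22
P. subalpina	Rothwald	Austria	M	43	23	12	11		23	0.70	*
P. subalpina	Derberence	Switzerland	M	37	26	11	15		26	1.66	***
P. subalpina	Valcartier	Canada	M	35	30	17	13		28	0.48
P. subalpina	Bodmeren	Switzerland	M	90	54	23	31		44	0.58
P. subalpina	Scatle	Switzerland	M	118	74	42	32		71	0.71	**
P. subalpina	Alpes Maritimes	France	M	125	75	46	29	*	75	0.58	*
P. subalpina	Campolino	Italia	M	138	79	43	36		86	0.41
P. subalpina	Kevo	Finland	M	138	87	44	43		72	0.52	*
P. fortinii s.s.	Glentanar	Scottland	M	10	5	3	2
P. fortinii s.s.	Bodmeren	Switzerland	M	10	8	4	4
P. fortinii s.s.	Marsh Island	USA	M	17	10	5	5		10	-0.17
P. fortinii s.s.	Noonday	USA	M	11	7	2	5
P. fortinii s.s.	Hill of Fare	Scottland	M	23	15	9	6		13	-0.07
P. fortinii s.s.	Valcartier	Canada	M	23	17	8	9		15	0.37
P. fortinii s.s.	Etang de la Gruere	Switzerland	M	24	18	10	8		23	0.29
P. fortinii s.s.	Bialowieza	Poland	M	92	51	35	16	*	51	0.05
P. fortinii s.s.	La Fage	France	M	102	37	16	21		38	0.23
P. fortinii s.s.	Le Pirou	France	M	13	11	4	7		11	0.22
P. fortinii s.s.	Tschornohora	Ukraine	M	76	41	28	13	*	41	0.25
P. fortinii s.s.	Kevo	Finland	M	100	54	24	30		54	0.28
CSP8	Global	Global	M	42	20	9	11
CSP9	Global	Global	M	10	5	4	1	n.a.
CSP10	Global	Global	M	30	5	4	1	n.a.
CSP11	Fuji	Japan	M	20	11	7	4		11	0.59
CSP11	Kevo	Finland	M	12	7	4	3	n.a.
CSP12	Creux du Van	Switzerland	M	15	7	5	2	n.a.
CSP12	Chychkan	Kirgistan	M	9	7	6	1	n.a.
CSP13	Creux du Van	Switzerland	M	43	23	9	12		23	0.66
CSP13	Alaska	USA	M	14	10	7	3		11	0.41
CSP14	Kevo	Finland	M	16	14	4	10		14	-0.18
CSP14	Creux du Van	Switzerland	M	21	8	6	2	n.a.
CSP14	Zinal_Baiting	Switzerland	M	72	26	14	12		25	-0.19
CSP15	Noonday	USA	M	28	14	6	8		15	-0.7
CSP16	Creux du Van	Switzerland	M	9	3	2	1	n.a.
CSP18	Global	Global	M	20	4	1	3	n.a.
CSP19	Global	Global	M	30	5	4	1	n.a.
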