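variant_id	effect_allele	other_allele	eaf	beta	se	pval	n
rs10520531	G	A	0.401	-0.0576	0.0087	4.48E-11	34217
rs105205419	G	A	0.6506	0.0479	0.0087	3.58E-08	34217
rs10520555	G	A	0.1761	-0.0719	0.0124	7.51E-09	34217
rs105205616	A	G	0.3057	0.0609	0.0095	1.28E-10	34217
rs10520571	A	G	0.405	0.0536	0.0088	1.34E-09	34217
rs105205811	T	C	0.1281	0.08	0.0145	3.33E-08	34217
rs10520597	A	G	0.2264	0.0759	0.0102	9.25E-14	34217
rs105206012	C	T	0.5479	-0.0751	0.0098	2.17E-14	34217
rs105206112	T	C	0.3814	-0.0495	0.0089	3.21E-08	34217
rs10520627	T	C	0.2277	-0.0656	0.0113	6.55E-09	34217
rs105206315	A	G	0.333	0.0519	0.0094	2.88E-08	34217
rs10520646	A	G	0.1372	0.0832	0.014	2.83E-09	34217
rs10520654	C	T	0.3078	0.0564	0.0092	7.43E-10	34217
rs10520664	T	A	0.3257	0.0784	0.0096	3.50E-16	34217
rs105206712	C	A	0.407	-0.0484	0.0089	4.93E-08	34217
rs10520689	T	C	0.5355	0.0514	0.0084	1.05E-09	34217
rs105206913	G	A	0.7614	0.0615	0.0101	9.19E-10	34217
rs105207017	C	T	0.188	0.0893	0.0162	3.63E-08	34217
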