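entry	substrate	relative_activity_pct	sd
1	Iminodiacetonitrile	21	1
2	Acrylonitrile	17	1
3	2-Methylglutaronitrile	25	3
4	Succinonitrile	5	1
5	Fumaronitrile	78	3
6	Malononitrile	17	1
7	Valeronitrile	4	1
8	3-Hydroxyglutaronitrile	N.D.
9	4-Chlorobutyronitrile	11	1
10	Glycolonitrile	69	4
11	3-Phenylpropionitrile	N.D.
12	Benzonitrile	N.D.
13	Cinnamonitrile	N.D.
14	Phenylacetonitrile	100	4
15	2-Chloromandelonitrile	298	7
16	1,2-Phenylenediacetonitrile	37	5
17	2-Phenylbutyronitrile	N.D.
18	alpha-Methylphenylacetonitrile	N.D.
19	Mandelonitrile	884	7
20	3-Cyanopyridine	N.D.
21	Thiophene-3-carbonitrile	1	1
22	Indole-3-acetonitrile	20	1
23	2-Cyanopyridine	7	1
24	4-Cyanopyridine	7	1
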