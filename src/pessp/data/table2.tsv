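nitrilase	organism	accession	specific_activity_u_mg	sd	ee_pct	amide_pct
BCJ2315	Burkholderia cenocepacia J2315	YP_002231697	27.79	1	98.4	N.D.
SWRW1	Sphingomonas wittichii RW1	YP_001261492	4.60	0.3	96.4	N.D.
MPPM1	Methylibium petroleiphilum PM1	YP_001020190	7.67	0.5	93.4	N.D.
SA12614	Stappia aggregata IAM 12614	ZP_01549810	3.87	0.3	92.8	8
NF10152	Nocardia farcinica IFM 10152	YP_119480	10.11	0.7	91.5	N.D.
BSBTAi1	Bradyrhizobium sp. BTAi1	YP_001240698	5.82	0.5	90.9	N.D.
BS278	Bradyrhizobium sp. ORS 278	YP_001206496	1.33	0.06	89.7	N.D.
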