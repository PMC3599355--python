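accession	organism	predicted_function	defined_function	identity_pct	citation
NP_773042	Bradyrhizobium japonicum USDA 110		nitrilase	100	B21
YP_559838	Burkholderia xenovorans LB400		nitrilase	60	B22
AAW79573	Pseudomonas fluorescens EBC191		nitrilase	60	B17
YP_001261492	Sphingomonas wittichii RW1	unnamed protein product		58	this study
YP_001206496	Bradyrhizobium sp. ORS 278	aliphatic nitrilase		58	this study
YP_001240698	Bradyrhizobium sp. BTAi1	aliphatic nitrilase		57	this study
AAR97509	uncultured organism		nitrilase	56	B20
YP_002231697	Burkholderia cenocepacia J2315	putative nitrilase		56	this study
YP_001020190	Methylibium petroleiphilum PM1	aliphatic nitrilase		55	this study
YP_119480	Nocardia farcinica IFM 10152	nitrilase		55	this study
ZP_01549810	Stappia aggregata IAM 12614	nitrilase		53	this study
Q02068	Rhodococcus rhodochrous K22		nitrilase	51	B27
Q03217	Rhodococcus rhodochrous J1		nitrilase	50	B23
ABD98457	Acidovorax facilis 72W		nitrilase	49	B25
P20960	Alcaligenes faecalis JM3		nitrilase	47	B13
YP_001264656	Sphingomonas wittichii RW1	unnamed protein product		46	this study
XP_001261815	Neosartorya fischeri NRRL 181	nitrilase, putative		45	this study
XP_001276027	Aspergillus clavatus NRRL 1	nitrilase, putative		41	this study
ABX75546	Aspergillus niger		nitrilase	38	B28
NP_887662	Bordetella bronchiseptica RB50	unnamed protein product		37	this study
YP_946154	Arthrobacter aurescens TC1	nitrilase		36	this study
ZP_03055417	Bacillus pumilus ATCC 7061	nitrilase		36	this study
NP_949502	Rhodopseudomonas palustris CGA009	nitrilase		36	this study
YP_260565	Pseudomonas fluorescens Pf-5	carbon-nitrogen family hydrolase		36	this study
NP_190018	Arabidopsis thaliana		nitrilase	35	B29
ZP_02885032	Burkholderia graminis C4D1M	nitrilase		35	this study
NP_770037	Bradyrhizobium japonicum USDA 110		nitrilase	35	B30
NP_197622	Arabidopsis thaliana		nitrilase	35	B31
YP_001022666	Methylibium petroleiphilum PM1	nitrilase		34	this study
NP_442646	Synechocystis sp. PCC 6803		nitrilase	34	B24
YP_001861308	Burkholderia phymatum STM815	unnamed protein product		34	this study
NP_190016	Arabidopsis thaliana		nitrilase	34	B29
NP_851011	Arabidopsis thaliana		nitrilase	34	B29
YP_001502716	Shewanella pealeana ATCC 700345	nitrilase		33	this study
YP_559598	Burkholderia xenovorans LB400	nitrilase		32	this study
ZP_05099070	Roseobacter sp. GAI101	aliphatic nitrilase		32	this study
YP_772488	Burkholderia ambifaria AMMD	nitrilase/cyanide hydratase hydratase and apolipoprotein N-acyltransferase		31	this study
YP_260015	Pseudomonas fluorescens Pf-5		nitrilase	31	B26
YP_162942	Zymomonas mobilis ZM4	unnamed protein product		30	this study
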