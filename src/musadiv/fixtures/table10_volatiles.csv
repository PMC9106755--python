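retention_time,compound,reference_ri,experimental_ri,chemical_class,Rajeli,Borkal Baista,Ankur,Bhurkel,Karpuravalli,Bluggoe,Birbutia,Ardhapuri,Grand Nain
4.624,"Acetic acid, butyl ester",781,785,ester,0,0,0,1,1,0,0,0,0
4.672,"Butanoic acid, ethyl ester",782,785,ester,0,1,0,0,0,0,0,0,0
6.557,"1-Butanol, 3-methyl-, acetate",865,855,ester,0,1,1,1,1,0,0,0,0
6.931,"n-Butyl ether",881,880.2,ester,0,0,0,0,0,0,1,0,0
8.108,"2-Buten-1-ol, 3-methyl-, acetate",916,905,ester,1,0,0,0,0,0,0,0,0
9.617,"Butanoic acid, 2-methylpropyl ester",949,953,ester,1,1,1,0,1,0,0,1,0
11.637,"Butanoic acid, butyl ester",994,995,ester,1,1,1,1,1,0,0,0,0
12.146,"Butanoic acid, 3-methyl-, 2-methylpropyl ester",1004,990,ester,0,1,0,0,0,0,0,0,0
12.539,"Acetic acid, hexyl ester",1011,1008,ester,0,0,1,1,1,0,0,0,0
12.547,"Propanoic acid, 2-methyl-, pentyl ester",1011,1019,ester,1,1,0,0,0,0,0,0,0
12.86,"4-Hexen-1-ol, (4E)-, acetate",1016,1013,ester,0,0,1,1,0,0,0,0,0
13.183,"Butanoic acid, 1-methylbutyl ester",1022,1019,ester,0,1,0,0,1,0,0,1,1
14.442,"Butanoic acid, 3-methyl-, butyl ester",1043,1044,ester,1,1,1,0,1,0,1,1,1
15.18,"Butanoic acid, pentyl ester",1056,1055,ester,1,1,1,1,1,0,1,0,0
17.592,"Butanoic acid, 2-pentenyl ester, (Z)-",1098,1091,ester,0,0,1,0,1,0,0,0,0
18.072,"Pentanoic acid, 3-methylbutyl ester",1105,1104,ester,1,1,1,0,1,0,1,0,0
19.39,"Hexanoic acid, 3-hydroxy-, ethyl ester",1126,1124,ester,0,0,1,1,1,0,0,0,0
21.037,"Pentanoic acid, pentyl ester",1199,1183,ester,0,1,1,0,1,0,0,0,0
23.494,"Hexanoic acid, butyl ester",1190,1183,ester,0,0,1,1,1,0,0,0,0
23.524,"Butanoic acid, hexyl ester",1190,1183,ester,0,1,0,0,0,0,0,0,1
23.8,"2-Butenoic acid, hexyl ester",1194,1191,ester,1,0,0,0,0,0,0,0,0
24.1,"Butanoic acid, 4-hexen-1-yl ester",1199,1191,ester,0,1,1,0,1,0,0,0,0
24.973,"Isopentyl hexanoate",1212,1218,ester,0,1,1,0,1,0,0,0,0
26.476,"Benzene, 1,4-dimethoxy-2-methyl",1235,1229,ester,1,0,0,0,0,0,0,0,0
26.895,"Hexyl n-valerate",1242,1235,ester,0,1,1,0,0,0,0,1,1
27.309,"Isopentyl hexanoate",1248,1253,ester,1,1,1,1,1,1,1,1,1
33.291,"2(3H)-Furanone, dihydro-5-pentyl-",1341,1341,ester,0,1,0,0,0,0,0,0,0
36.05,"5-Dodecen-1-ol, acetate, (Z)-",1386,1389,ester,0,0,0,0,0,0,0,1,1
36.58,"Decanoic acid, ethyl ester",1394,1393,ester,1,0,0,0,0,0,0,0,0
58.383,"Phthalic acid, isobutyl 2-pentyl ester",2069,2008,ester,1,1,1,1,1,1,1,1,1
5.913,"2-Hexenal",846,838,aromatic aldehyde,1,1,1,1,0,1,0,0,0
26.334,"Propanal, 3-cyclohexylidene-2-methyl-",1233,1227,aromatic aldehyde,0,1,0,0,0,0,0,0,0
18.018,"2-Nonen-1-ol",1102,1105,alcohol,0,0,0,1,0,1,0,0,0
24.501,"3-Decan-1-ol, (E)-",1205,1233,alcohol,0,0,0,1,0,0,1,0,0
31.8,"1-Decanol, 2-ethyl-",1317,1350,alcohol,1,0,0,0,0,0,0,0,0
36.833,"1-Octanol, 2-butyl-",1398,1393,alcohol,0,1,0,0,1,0,1,0,0
42.895,"1-Decanol, 2-hexyl-",1496,1504,alcohol,1,1,1,1,0,1,1,0,0
44.713,"2-Hexyl-1-octanol",1590,1591,alcohol,1,0,0,1,0,0,1,0,0
53.536,"1-Hexadecanol, 2-methyl-",1899,1890,alcohol,1,1,0,1,1,1,1,0,0
4.165,"1,3,5-Cycloheptatriene",765,771,hydrocarbon,0,0,0,0,0,0,1,0,0
31.769,"Decane, 2,4,6-trimethyl-",1316,1318,hydrocarbon,0,1,0,0,0,0,1,0,0
33.325,"Tridecane, 5-methyl-",1342,1349,hydrocarbon,1,0,1,0,0,0,0,0,0
38.733,"2-Butanone, 4-(2,6,6-trimethyl-1-cyclohexen-1-yl)-",1429,1427.8,ketone,1,0,0,1,1,0,1,0,0
39.722,"5,9-Undecadien-2-one, 6,10-dimethyl-, (E)-",1445,1453,ketone,1,1,0,1,0,0,1,0,0
26.476,"Benzene, 1,4-dimethoxy-2-methyl",1235,1229,ether,1,0,0,0,0,0,0,0,0
36.929,"Benzene, 1,2-dimethoxy-4-(2-propenyl)-",1400,1402,ether,0,0,0,0,0,1,0,0,0
45.776,"Benzene, 1,2,4-trimethoxy-5-(1-propenyl)-, (Z)-",1622,1640,ether,1,1,1,1,1,1,1,1,1
33.442,"2,2-Dimethylglutaric acid",1344,1345,carboxylic acid,0,0,0,0,1,0,0,0,0
30.263,"2H-Pyran-2,3-diol, tetrahydro-, diacetate, cis-",1293,1364,diverse functional group,0,1,1,0,0,0,0,0,0
33.783,"Eugenol",1349,1337,diverse functional group,0,0,0,0,0,0,0,1,1
35.877,"Carbonic acid, dipentyl ester",1383,1358,diverse functional group,0,1,0,0,0,0,0,0,0
38.389,"Chloroacetic acid, 2-ethylcyclohexyl ester",1423,1433,diverse functional group,0,0,0,0,0,0,0,1,0
51.206,"2-Propenoic acid, 3-(3,4-dimethoxyphenyl)-, (E)-",1774,1735,diverse functional group,1,1,0,0,1,1,0,0,0
56.803,"Octadecane, 1-chloro-",2037,2036,chlorine-containing,0,0,1,1,0,0,0,0,0
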