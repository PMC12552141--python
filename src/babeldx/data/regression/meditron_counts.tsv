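language	top1	top3	top10	not_ranked	no_diagnosis
fr	751	1094	1229	3688	0
es	755	1117	1358	3559	0
ja	833	1181	1293	3624	0
de	752	1088	1309	3608	0
nl	782	1118	1379	3538	0
zh	810	1105	1176	3741	0
tr	670	978	1178	3739	0
cs	659	1006	1180	3737	0
en	756	1028	1141	3776	0
it	767	1089	1310	3607	0
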