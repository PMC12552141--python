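language	top1	top3	top10	not_ranked	no_diagnosis
en	978	1328	1532	3384	1
es	941	1355	1560	3357	0
cs	880	1240	1396	3495	26
tr	978	1373	1544	3265	108
de	938	1290	1439	3377	101
it	851	1314	1498	3416	3
zh	909	1338	1401	3510	6
nl	1006	1357	1503	3391	23
ja	790	1245	1352	3318	247
fr	918	1338	1524	3388	5
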