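patient,age,gender,implantation_site,n_days,n_ieeg_files,n_ictal_patterns
1,21,F,thalamus,95,349,11
2,22,M,developmental_malformation,166,333,13
3,42,F,neocortex,677,1682,430
4,22,F,hippocampus,393,1316,452
5,39,F,hippocampus,314,716,73
6,29,M,developmental_malformation,152,294,9
7,22,F,hippocampus,461,1396,567
8,34,F,neocortex,600,1172,113
9,24,M,neocortex,425,1304,258
10,19,F,thalamus,355,16,5
11,39,F,developmental_malformation,297,834,720
12,31,M,hippocampus,261,443,47
13,46,M,hippocampus,17,46,4
14,53,M,neocortex,42,90,1
15,22,M,thalamus,171,529,13
16,63,F,neocortex,732,4110,2057
17,35,F,neocortex,19,95,4
18,37,M,neocortex,735,508,20
19,31,F,thalamus,73,299,9
20,38,F,hippocampus,202,522,93
21,30,M,hippocampus,376,796,159
22,47,F,developmental_malformation,783,1518,168
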