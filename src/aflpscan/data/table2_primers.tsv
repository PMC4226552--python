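primer	n_markers	n_outliers	outlier_ids
ACag	201	9	33;77;84;85;119;136;186;187;200
ACtc	175	2	21;94
ACtt	157	5	40;76;79;115;142
AGaa	147	4	5;56;60;101
AGac	200	7	3;13;84;144;161;188;190
AGtg	141	4	97;103;106;126
CAat	210	5	102;103;145;166;181
CAta	185	8	73;84;116;155;157;158;165;169
CCac	195	4	17;129;153;167
CCta	219	3	88;153;213
CCtt	256	12	2;34;41;42;50;67;97;158;168;169;193;208
CGag	101	4	67;69;70;97
CGtt	86	6	24;40;50;51;79;87
CTaa	239	11	3;7;78;86;166;173;184;185;187;208;232
CTag	208	9	64;90;102;125;132;133;147;154;176
CTtg	211	10	46;93;97;104;117;133;170;174;175;187
GCat	224	12	15;31;60;106;169;175;180;181;192;208;212;213
GCta	199	6	7;20;33;82;98;187
GCtc	181	7	16;22;40;43;160;166;172
GGac	168	4	30;31;36;164
GGtc	136	6	15;18;64;85;125;129
Total	3839	138
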