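population_id	country	location	n	latitude	longitude	fst	fst_lo	fst_hi	fis	fis_lo	fis_hi	variable_pct	diversity
BSt	Belgium	Stalhille	21	51°13'N	3°05'E	0.304	0.292	0.318	0.0010	0.0000	0.0029	30.2	0.091
BVe	Belgium	Veurne	21	51°03'N	2°40'E	0.345	0.331	0.359	0.0008	0.0000	0.0024	25.3	0.078
CZD	Czech Republic	Drnholec	21	48°53'N	16°27'E	0.162	0.151	0.172	0.0431	0.0288	0.0576	46.3	0.132
FAv	France	Avallon	20	47°29'N	3°54'E	0.248	0.236	0.261	0.0008	0.0000	0.0023	37.3	0.115
FCm	France	Clermont-Ferrand	21	45°47'N	3°05'E	0.262	0.250	0.275	0.0006	0.0000	0.0018	38.1	0.116
FFr	France	Fressenneville	22	50°05'N	1°34'E	0.302	0.289	0.315	0.0020	0.0001	0.0058	30.8	0.090
FTh	France	Thaon	21	49°16'N	0°26'W	0.294	0.281	0.306	0.0058	0.0004	0.0137	35.4	0.108
DGo	Germany	Gotha	20	50°57'N	10°42'E	0.224	0.212	0.235	0.0238	0.0118	0.0382	37.6	0.113
DSc	Germany	Schiltach	20	48°17'N	8°21'E	0.237	0.225	0.250	0.0007	0.0000	0.0022	33.8	0.107
INa	Italy	Naturno	21	46°39'N	11°01'E	0.349	0.335	0.363	0.0030	0.0002	0.0083	31.6	0.096
PSr	Poland	Srodkowy	21	53°35'N	22°47'E	0.297	0.283	0.309	0.0055	0.0000	0.0136	34.2	0.108
EAv	Spain	Avila	21	40°42'N	4°48'W	0.426	0.411	0.440	0.0009	0.0000	0.0026	27.8	0.084
ESe	Spain	Segovia	21	40°54'N	4°06'W	0.442	0.429	0.457	0.0006	0.0000	0.0019	26.1	0.078
CHAP	Switzerland	Alp di Plaun	20	46°47'N	9°29'E	0.224	0.212	0.236	0.0129	0.0001	0.0240	39.3	0.123
CHBo	Switzerland	Bonaduz	22	46°48'N	9°24'E	0.297	0.285	0.310	0.0050	0.0000	0.0125	32.3	0.098
CHBw	Switzerland	Brienzwiler	21	46°45'N	8°07'E	0.328	0.315	0.343	0.0031	0.0000	0.0085	27.7	0.082
CHCa	Switzerland	Calandahütte	22	46°53'N	9°29'E	0.257	0.245	0.269	0.0124	0.0003	0.0232	35.5	0.105
CHDP	Switzerland	Domat/Ems	22	46°50'N	9°26'E	0.278	0.265	0.290	0.0061	0.0000	0.0145	32.6	0.097
CHGS	Switzerland	Grosse Scheidegg	22	46°40'N	8°06'E	0.386	0.372	0.400	0.0011	0.0000	0.0034	22.6	0.068
CHMe	Switzerland	Meiringen	22	46°43'N	8°11'E	0.411	0.396	0.424	0.0007	0.0000	0.0021	19.9	0.061
CHSF	Switzerland	Schreck-Feld	22	46°40'N	8°04'E	0.354	0.341	0.368	0.0019	0.0001	0.0055	25.1	0.076
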