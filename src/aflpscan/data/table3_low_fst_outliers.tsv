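marker_id	po	fst	marker_freq	allele_freq	category
CCta185	226.3	0.105	0.991	0.843	bimodal_balancing
CGag21	inf	0.057	0.918	0.764	bimodal_balancing
CTaa125	63.1	0.136	0.927	0.699	bimodal_balancing
CTaa235	14.0	0.157	0.813	0.618	bimodal_balancing
GCat153	inf	0.094	0.723	0.476	bimodal_balancing
GCtc42	118.0	0.120	0.904	0.770	bimodal_balancing
CAta44	inf	0.032	1	0.738	bimodal_no_per_pop
GCtc76	inf	0.029	0.984	0.847	bimodal_no_per_pop
ACtc64	999.0	0.063	0.995	0.972	uni_multimodal
AGaa48	554.6	0.084	1	0.844	uni_multimodal
AGaa96	22.5	0.153	0.785	0.546	uni_multimodal
AGtg79	130.6	0.117	0.941	0.728	uni_multimodal
CAat185	249.0	0.078	0.969	0.812	uni_multimodal
CAta9	inf	0.035	1	0.940	uni_multimodal
CAta91	32.1	0.107	0.932	0.783	uni_multimodal
CCta61	28.6	0.126	0.934	0.761	uni_multimodal
GCat12	inf	0.033	1	0.982	uni_multimodal
GCat95	inf	0.054	0.913	0.739	uni_multimodal
GCat152	1249	0.075	0.93	0.740	uni_multimodal
GCta26	91.6	0.124	0.888	0.696	uni_multimodal
GCtc48	12.1	0.148	0.857	0.596	uni_multimodal
ACag100	134.1	0.113	0.226	0.131	low_frequency
CCac84	11.2	0.120	0.052	0.049	low_frequency
CCta81	27.9	0.105	0.074	0.044	low_frequency
CCta90	59.2	0.100	0.064	0.052	low_frequency
CCta180	31.5	0.102	0.06	0.037	low_frequency
CCta184	10.7	0.127	0.065	0.043	low_frequency
CCtt32	10.1	0.132	0.07	0.054	low_frequency
CCtt65	inf	0.078	0.33	0.206	low_frequency
CCtt131	39.3	0.109	0.119	0.082	low_frequency
CCtt145	383.6	0.068	0.075	0.074	low_frequency
CGtt4	16.5	0.139	0.204	0.123	low_frequency
CGtt6	40.0	0.109	0.098	0.069	low_frequency
ACtc47	inf	0.066	0.991	0.812	sex_linked
ACtt16	inf	0.026	1	0.787	sex_linked
ACtt18	105.4	0.120	0.881	0.734	sex_linked
ACtt31	inf	0.024	0.998	0.762	sex_linked
ACtt46	276.8	0.121	0.938	0.713	sex_linked
AGac127	inf	0.079	0.998	0.829	sex_linked
AGtg131	160.3	0.135	0.78	0.596	sex_linked
CAat112	33.2	0.144	0.847	0.618	sex_linked
CAta114	inf	0.024	0.986	0.744	sex_linked
CAta142	inf	0.068	0.961	0.772	sex_linked
CCac46	inf	0.038	0.995	0.747	sex_linked
CCac57	inf	0.029	1	0.763	sex_linked
CCta11	inf	0.024	1	0.752	sex_linked
CCta29	34.7	0.148	0.66	0.477	sex_linked
CCta73	12.4	0.101	0.998	0.983	sex_linked
CCtt100	inf	0.031	0.991	0.710	sex_linked
CCtt150	inf	0.042	0.998	0.757	sex_linked
CCtt191	inf	0.029	0.995	0.712	sex_linked
CTaa27	inf	0.040	0.984	0.775	sex_linked
CTaa102	inf	0.040	0.934	0.662	sex_linked
CTaa113	inf	0.049	1	0.780	sex_linked
CTag19	inf	0.045	1	0.772	sex_linked
CTag94	inf	0.027	0.998	0.797	sex_linked
CTtg10	inf	0.076	0.896	0.738	sex_linked
CTtg105	inf	0.038	0.971	0.730	sex_linked
CTtg155	inf	0.059	0.943	0.721	sex_linked
GCat44	inf	0.068	0.946	0.778	sex_linked
GCat69	inf	0.023	0.995	0.742	sex_linked
GCat98	inf	0.044	0.995	0.792	sex_linked
GCta14	inf	0.060	1	0.817	sex_linked
GCta96	4999	0.090	0.895	0.632	sex_linked
ACag54	262.2	0.125	0.576	0.831	sex_linked
AGtg13	13.4	0.153	0.444	0.301	sex_linked
GGtc1	inf	0.033	0.998	0.866	batch_artifact
GGtc9	45.3	0.122	0.988	0.748	batch_artifact
GGtc10	inf	0.047	0.995	0.981	batch_artifact
GGtc21	4999	0.097	0.846	0.714	batch_artifact
GGtc34	16.2	0.089	0.995	0.968	batch_artifact
GGtc37	inf	0.023	0.998	0.863	batch_artifact
GGtc55	inf	0.057	0.998	0.817	batch_artifact
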