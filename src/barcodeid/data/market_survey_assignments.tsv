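sample_id	candidate_species	avg_distance	pct_coverage	pct_identity
IIL04	Carcharhinus brachyurus	0.001	98	99
IIL05	Carcharhinus brachyurus	0.001	97	99
IIL14	Carcharhinus brachyurus	0.001	98	99
IIL04-2	Carcharhinus falciformis	0.003	98	99
IIL27	Carcharhinus falciformis	0.003	99	99
FA08	Galeorhinus galeus	0.001	95	99
MP60	Genidens barbus	NC	96	100
E14	Gymnura altavela	0.020	99	99
IIL37	Gymnura altavela	0.021	98	99
IIL36	Myliobatis goodei	0.013	96	99
E13	Narcine brasiliensis	0.003	99	99
IIL15	Prionace glauca	0.001	99	99
IIL30	Prionace glauca	0.000	99	99
IIL31	Prionace glauca	0.000	100	100
IIL34	Prionace glauca	0.000	100	99
IIL35	Prionace glauca	0.000	100	99
O22	Prionace glauca	0.000	97	100
FA02	Prionace glauca	0.002	100	99
FA03	Prionace glauca	0.000	96	100
FA23	Prionace glauca	0.000	99	100
FA24	Prionace glauca	0.002	100	99
FA25	Prionace glauca	0.003	100	99
FA26	Prionace glauca	0.000	100	100
FA27	Prionace glauca	0.000	100	99
FA29	Prionace glauca	0.000	100	100
FA31	Prionace glauca	0.000	100	99
IIL26	Rajiformes sp. BOLD AABB	0.000	96	100
E34	Pseudobatos horkelii	0.003	97	100
E36	Pseudobatos horkelii	0.002	98	100
E26	Rhizoprionodon lalandii	0.001	94	100
IIL13	Rhizoprionodon lalandii	0.001	99	99
FA05	Rhizoprionodon lalandii	0.001	91	99
FA17	Rhizoprionodon lalandii	0.001	100	99
O24	Rhizoprionodon porosus	0.001	95	100
E07	Sphyrna lewini	0.024	100	100
E08	Sphyrna lewini	0.021	98	99
E15	Sphyrna lewini	0.022	97	100
E44	Sphyrna lewini	0.021	97	99
MG04	Sphyrna lewini	0.034	97	99
MP55	Sphyrna lewini	0.024	100	99
MP57	Sphyrna lewini	0.023	97	100
MP58	Sphyrna lewini	0.022	97	100
O06	Sphyrna lewini	0.022	97	99
O07	Sphyrna lewini	0.021	97	100
O08	Sphyrna lewini	0.022	98	100
O09	Sphyrna lewini	0.024	100	99
O27	Sphyrna lewini	0.024	100	100
O29	Sphyrna lewini	0.021	99	100
O28	Sphyrna zygaena	0.000	100	99
FA21	Sphyrna zygaena	0.001	100	100
MP15	Squalus cubensis	0.000	98	100
MP18	Squalus mitsukurii	0.001	98	100
MP16	Squalus mitsukurii	0.001	96	100
FA16	Squatina guggenheim	0.001	96	100
MG08	Squatina occulta	0.000	95	100
IIL01	Xiphias gladius	NC	100	99
IIL03	Xiphias gladius	NC	100	99
IIL16	Xiphias gladius	NC	100	99
IIL18	Xiphias gladius	NC	100	99
IIL19	Xiphias gladius	NC	100	100
IIL25	Xiphias gladius	NC	100	100
E50	Zapteryx brevirostris	0.030	97	99
E54	Zapteryx brevirostris	0.000	100	100
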