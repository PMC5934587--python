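species	group
Carcharhinus brachyurus	Carcharhiniformes
Carcharhinus falciformis	Carcharhiniformes
Galeorhinus galeus	Carcharhiniformes
Prionace glauca	Carcharhiniformes
Rhizoprionodon lalandii	Carcharhiniformes
Rhizoprionodon porosus	Carcharhiniformes
Sphyrna lewini	Carcharhiniformes
Sphyrna zygaena	Carcharhiniformes
Squalus cubensis	Squaliformes
Squalus mitsukurii	Squaliformes
Squatina guggenheim	Squatiniformes
Squatina occulta	Squatiniformes
Pseudobatos horkelii	Rhinopristiformes
Zapteryx brevirostris	Rhinopristiformes
Gymnura altavela	Myliobatiformes
Myliobatis goodei	Myliobatiformes
Rajiformes sp. BOLD AABB	Rajiformes
Narcine brasiliensis	Torpediniformes
Genidens barbus	Teleostei
Xiphias gladius	Teleostei
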