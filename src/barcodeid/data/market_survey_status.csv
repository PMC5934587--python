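species,common_name,status_global,status_national,status_regional_1,status_regional_2
Carcharhinus brachyurus,copper shark,NT,DD,absent,absent
Carcharhinus falciformis,silky shark,NT,NT,absent,absent
Galeorhinus galeus,school shark,VU,CR,CR,absent
Gymnura altavela,butterfly ray,VU,CR,EN,absent
Myliobatis goodei,southern eagle ray,DD,CR,CR,absent
Narcine brasiliensis,Brazilian electric ray,DD,DD,absent,absent
Prionace glauca,blue shark,NT,NT,VU,absent
Pseudobatos horkelii,Brazilian guitarfish,CR,CR,CR,CR
Rhizoprionodon lalandii,Brazilian sharpnose shark,DD,NT,absent,absent
Rhizoprionodon porosus,Caribbean sharpnose shark,LC,DD,absent,absent
Sphyrna lewini,scalloped hammerhead shark,EN,CR,CR,EN
Sphyrna zygaena,smooth hammerhead,VU,CR,CR,EN
Squalus cubensis,Cuban dogfish,DD,absent,absent,absent
Squalus mitsukurii,shortspine spurdog,DD,DD,absent,absent
Squatina guggenheim,spiny angel shark,EN,CR,CR,EN
Squatina occulta,smoothback angel shark,EN,CR,CR,absent
Zapteryx brevirostris,shortnose guitarfish,VU,VU,CR,absent
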