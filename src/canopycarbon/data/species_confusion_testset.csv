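predicted,Abies alba,Angiosperm,Picea abies,Larix decidua,Pinus cembra,Pinus nigra,Pinus sylvestris
Abies alba,32,2,46,7,0,0,0
Angiosperm,3,483,44,18,4,0,0
Picea abies,7,7,683,18,1,0,0
Larix decidua,0,36,83,334,10,2,0
Pinus cembra,0,1,2,0,41,0,0
Pinus nigra,0,0,0,2,0,14,0
Pinus sylvestris,0,0,0,0,0,0,3
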