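species,alpha,beta,gamma,delta,d0,wd,carbon_fraction,group,source
All,0.094,1.0,1.90,1.00,0.0,0.43,0.50,conifer,synthetic placeholder - replace with regional table
Picea abies,0.092,1.0,1.92,1.02,0.0,0.40,0.50,conifer,synthetic placeholder - replace with regional table
Abies alba,0.095,1.0,1.88,1.05,0.0,0.40,0.50,conifer,synthetic placeholder - replace with regional table
Larix decidua,0.090,1.0,1.95,0.95,0.0,0.55,0.50,conifer,synthetic placeholder - replace with regional table
Pinus cembra,0.098,1.0,1.85,0.98,0.0,0.42,0.50,conifer,synthetic placeholder - replace with regional table
Pinus sylvestris,0.096,1.0,1.87,0.97,0.0,0.42,0.50,conifer,synthetic placeholder - replace with regional table
Angiosperms,0.110,1.0,1.80,1.10,0.0,0.53,0.48,angiosperm,synthetic placeholder - replace with regional table
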