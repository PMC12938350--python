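tip	depth_class
Liparis_chefuensis	shallow
Liparis_punctulatus	shallow
Liparis_tessellatus	shallow
Liparis_agassizii	deep
Liparis_bathyarcticus	deep
Liparis_ochotensis	deep
Liparis_gibbus	deep
Liparis_tanakae	deep
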