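tip	pattern
Liparis_chefuensis	WYANC
Liparis_punctulatus	WYANC
Liparis_tessellatus	WYANC
Liparis_agassizii	WNCYAC
Liparis_bathyarcticus	WNCYAC
Liparis_ochotensis	WNCYAC
Liparis_gibbus	WNCYAC
Liparis_tanakae	WNCYAA
Careproctus_cypselurus	WANCY
Careproctus_phasma	WANCY
Careproctus_rastrinus	WANCY
Careproctus_reinhardti	WANCY
Careproctus_scottae	WANCY
Crystallichthys_cyclospilus	WANCY
Pseudoliparis_swirei	WANCY
Cottus_dzungaricus	WANCY
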