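(((Liparis_tessellatus,Liparis_punctulatus,Liparis_chefuensis),(Liparis_agassizii,Liparis_bathyarcticus,Liparis_ochotensis,Liparis_gibbus,Liparis_tanakae)),((Careproctus_cypselurus,Careproctus_phasma,Careproctus_rastrinus,Careproctus_reinhardti,Careproctus_scottae),Crystallichthys_cyclospilus,Pseudoliparis_swirei),Cottus_dzungaricus);
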