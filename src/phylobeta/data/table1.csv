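genus,occurrence,abundance
Alisotrichia,3,3
Anchitrichia,1,65
Atopsyche,1,2
Austrotinotes,3,5
Cernotina,8,12
Chimarra,31,288
Cyrnellus,2,2
Helicopsyche,29,219
Itauara,4,18
Leptonema,46,306
Macronema,34,132
Macrostemum,19,100
Marilia,27,144
Nectopsyche,14,60
Neotrichia,3,3
Ochrotrichia,15,31
Oecetis,16,42
Oxyethira,7,72
Phylloicus,27,121
Polyplectropus,5,8
Protoptila,5,7
Smicridea,47,338
Triplectides,18,42
Zumatrichia,5,7
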