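name,water,gelatin,lard,hydroxyapatite,sds
Skin,75.0,25.0,0,0,0
Muscle,74.78,19.97,5.0,0,0.25
Adipose,0,0,100,0,0
Spongiosa,26.61,11.83,47.43,12.81,1.32
45% HA bone,55.0,0,0,45.0,0
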