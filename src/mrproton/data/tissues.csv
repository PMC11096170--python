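name,measured_density,measured_rsp,mean_excitation_energy,H,C,N,O,Na,P,S,Ca
Skin,1.077,1.067,77.5,10.09,10.55,3.82,75.26,0,0,0.28,0
Muscle,1.064,1.056,76.7,10.37,12.44,3.06,73.86,0.02,0,0.25,0
Adipose,0.936,0.979,61.9,12.37,77.70,0.16,9.77,0,0,0,0
Spongiosa,1.091,1.076,76.1,9.79,42.50,1.88,37.96,0.11,2.37,0.28,5.11
45% HA bone,1.417,1.344,108.5,6.24,0,0,67.48,0,8.32,0,17.96
Brain,1.028,1.014,77.3,10.96,6.02,0.73,82.24,0.05,0,0,0
Liver,1.065,1.054,77.2,10.60,8.98,2.05,78.25,0.12,0,0,0
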