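symbol,atomic_number,atomic_mass,mean_excitation_energy
H,1,1.008,19.2
C,6,12.011,81.0
N,7,14.007,82.0
O,8,15.999,106.0
Na,11,22.990,149.0
P,15,30.974,173.0
S,16,32.06,180.0
Ca,20,40.078,191.0
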