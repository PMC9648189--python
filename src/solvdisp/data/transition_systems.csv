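system,reference_index,level,energy_hartree,mux,muy,muz
two-level,0,0,0.00,0.0,0.0,0.0
two-level,0,1,0.50,0.0,0.0,1.0
three-level-excited,1,0,0.00,0.40,0.0,0.90
three-level-excited,1,1,0.18,0.0,0.0,0.0
three-level-excited,1,2,0.55,0.30,0.50,0.0
five-level,0,0,0.00,0.0,0.0,0.0
five-level,0,1,0.375,0.0,0.0,1.2904
five-level,0,2,0.47,0.7416,0.0,0.0
five-level,0,3,0.53,0.0,0.5477,0.0
five-level,0,4,0.70,0.3651,0.3651,0.3651
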