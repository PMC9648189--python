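solute,state,b,ionization_hartree,vertical_ev
formaldehyde,ground,1.67,0.4043,0.0
formaldehyde,n-pi*,1.67,0.2503,4.19
acrolein,ground,1.60,0.3776,0.0
acrolein,n-pi*,1.60,0.2349,3.88
acrolein,pi-pi*,1.60,,6.93
acetone,ground,1.62,0.3634,0.0
acetone,n-pi*,1.61,0.1908,4.69
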