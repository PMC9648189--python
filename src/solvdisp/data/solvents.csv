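name,eta0,A2,A4,ionization_hartree,first_absorption_ev,contact_radius_default,contact_radius_on_O
water,1.32315,0.00201432,6.21176e-06,0.4638,,2.96,1.86
ethanol,1.35059,0.00226353,7.02316e-06,0.385133,,3.932,1.86
cyclohexane,1.41142,0.00259217,1.25986e-05,0.3631,7.44,5.20,5.20
chloroform,1.43108,0.00260712,3.60209e-05,0.41784,,4.82,4.82
carbon tetrachloride,1.44277,0.00332168,1.48334e-05,0.4215,,5.20,5.20
toluene,1.48437,0.0016524,0.000241204,0.3245,,5.01,5.01
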