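symbol,Z,A,density_g_cm3
H,1,1.008,8.375e-05
C,6,12.011,2.0
N,7,14.007,1.165e-03
O,8,15.999,1.332e-03
Na,11,22.990,0.971
Mg,12,24.305,1.74
P,15,30.974,1.82
S,16,32.06,2.07
Cl,17,35.45,3.214e-03
Ar,18,39.948,1.662e-03
K,19,39.098,0.862
Ca,20,40.078,1.55
Fe,26,55.845,7.874
I,53,126.904,4.93
Ba,56,137.327,3.62
Gd,64,157.25,7.90
Yb,70,173.045,6.90
Ta,73,180.948,16.65
Au,79,196.967,19.32
Bi,83,208.980,9.78
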