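volunteer,ethanol,exposure_ppm,blood_xylene,breath_xylene,urine_mha
A,no,45.5,1,1,1
B,no,45.5,0,1,1
C,no,45.5,1,1,1
D,no,45.5,1,1,1
E,no,44.1,0,1,1
F,no,44.1,0,1,1
G,no,44.1,0,1,1
H,no,44.1,0,1,1
A,yes,43.0,1,1,1
B,yes,43.0,1,1,1
C,yes,45.1,1,1,1
D,yes,43.0,1,1,1
E,yes,45.1,1,1,1
F,yes,45.1,1,1,1
G,yes,43.0,1,1,1
H,yes,45.1,1,1,1
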