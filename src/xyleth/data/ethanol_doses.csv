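volunteer,body_mass_kg,ethanol_g,absolute_volume_mL,final_volume_mL,gastric_halflife_h,ke_max_1_h
A,79,63,80,320,0.122,5.67
B,61.5,49,62,248,0.093,7.49
C,89,71,90,360,0.139,4.99
D,85,68,86,344,0.132,5.24
E,76,61,77,308,0.117,5.91
F,76,61,77,308,0.117,5.91
G,75,60,76,304,0.116,5.99
H,68,54,69,276,0.104,6.67
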