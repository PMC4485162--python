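volunteer,age,body_mass_kg,height_m,bmi_kg_m2,fat_fraction,alveolar_ventilation_L_h,urine_flow_L_h,urinary_creatinine_mmol_L,blood_air_pc_xylene
A,54,79,1.68,28.00,0.218,383.3,0.070,14.8,15.1
B,51,61.5,1.78,19.32,0.192,409.3,0.125,7.30,16.8
C,47,89,1.91,24.40,0.169,477.5,0.090,14.9,11.4
D,48,85,1.75,27.80,0.263,362.7,0.091,13.0,18.0
E,29,76,1.85,22.20,0.130,327.2,0.088,12.5,26.5
F,25,76,1.83,22.70,0.162,352.6,0.055,14.8,20.2
G,41,75,1.70,26.00,0.179,462.2,0.076,12.8,
H,29,68,1.70,23.50,0.299,348.6,0.074,10.2,21.6
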