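depth_cm,clay_pct,silt_pct,slll,sdul,ssat,srgf,ph,sloc_pct,sbdm
5,21,50,0.153,0.34,0.447,1,7.8,1.12,1.22
15,21,50,0.153,0.34,0.447,1,7.8,1.12,1.22
30,21,50,0.153,0.34,0.447,0.7,7.8,1.12,1.22
60,21,45,0.144,0.314,0.414,0.2,7.9,0.82,1.31
80,21,45,0.144,0.314,0.414,0.05,7.9,0.82,1.31
100,21,45,0.144,0.314,0.414,0.03,7.9,0.82,1.31
120,21,45,0.144,0.314,0.414,0.03,7.9,0.82,1.31
150,21,45,0.144,0.314,0.414,0.03,7.9,0.82,1.31
180,21,45,0.144,0.314,0.414,0.03,7.9,0.82,1.31
200,21,45,0.144,0.314,0.414,0.03,7.9,0.82,1.31
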