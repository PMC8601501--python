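name,default,calibrated
EM-FL,29,39.45
OPTBI,20,7.5
SLOBI,0.035,0.064
SLAVR,250,319.2
TRIFL,0.32,0.23
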