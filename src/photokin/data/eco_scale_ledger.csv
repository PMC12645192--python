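method,item,penalty_points
UV,"Citro-phosphate buffer (pH 7.0, 0.002 M)",0.0
UV,"Instrument energy consumption (kWh)",1.0
UV,Sonicator,0.0
UV,"Occupational hazards",0.0
UV,"Waste (>10.0 mL)",5.0
HPLC,"Citro-phosphate buffer (pH 7.0, 0.002 M)",0.0
HPLC,Acetonitrile,6.0
HPLC,"Instrument energy consumption (kWh)",2.0
HPLC,Sonicator,0.0
HPLC,"Occupational hazards",6.0
HPLC,"Waste (>10.0 mL)",5.0
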