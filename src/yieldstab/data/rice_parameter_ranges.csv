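name,min,max,unit
DVRI,0.000750,0.001100,degC d-1
DVRJ,0.000773,0.001231,degC d-1
DVRP,0.000719,0.001600,degC d-1
DVRR,0.001244,0.002184,degC d-1
RGRLMN,0.003013,0.005494,degC d-1
RGRLMX,0.0060,0.0090,degC d-1
WGRMX,19.0,30.0,mg grain-1
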