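name,min,max,unit
aMaxI,-50,50,-
aMaxS,1,20,-
aX0,0.5,0.9,-
dm_per_seed,0.0001,0.001,g
main_stem_coef,1,3.5,degC-1
maxGFRate,0.001,0.05,mg degC d-1
rue,1.3,2.0,g MJ-1
spla_intercept,-250,-100,degC-1
spla_prod_coef,0.001,0.010,degC-1
tilleringPropensity,1.5,50,-
tillerSdSlope,0.1,0.5,-
tpla_inflection_ratio,0.5,0.9,degC
tpla_prod_coef,0.01,0.04,degC-1
tt_emerg_to_endjuv,100,500,degC d-1
tt_endjuv_to_init,50,500,degC d-1
tt_flag_to_flower,50,500,degC d-1
tt_flower_to_maturity,200,800,degC d-1
tt_flower_to_start_grain,30,500,degC d-1
tt_maturity_to_ripe,1,100,degC d-1
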