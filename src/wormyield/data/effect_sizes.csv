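factor,category,sample_size,effect_percent,applies_to_map
crop_type,cereal_grains,106,31.41,true
crop_type,grasses,154,24.33,false
crop_type,legumes,42,9.19,true
soil_ph,low,93,33.43,true
soil_ph,medium,76,33.64,true
soil_ph,high,81,13.63,true
soil_texture,sandy,16,9.64,true
soil_texture,loamy,110,20.74,true
soil_texture,clayey,52,46.79,true
n_rate,low,183,19.00,true
n_rate,high,25,8.51,true
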