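parameter,gender,age,value
mean_height,M,0,50
mean_height,M,1,76
mean_height,M,2,88
mean_height,M,5,110
mean_height,M,10,138
mean_height,M,14,164
mean_height,M,18,176
mean_height,M,30,177
mean_height,M,99,174
mean_height,F,0,50
mean_height,F,1,74
mean_height,F,2,86
mean_height,F,5,109
mean_height,F,10,138
mean_height,F,14,160
mean_height,F,18,163
mean_height,F,30,163
mean_height,F,99,161
mean_bmi,M,0,13.4
mean_bmi,M,1,17.2
mean_bmi,M,2,16.5
mean_bmi,M,5,15.5
mean_bmi,M,10,17.5
mean_bmi,M,15,20.5
mean_bmi,M,18,22.5
mean_bmi,M,30,26.5
mean_bmi,M,60,28.0
mean_bmi,M,99,26.5
mean_bmi,F,0,13.3
mean_bmi,F,1,16.8
mean_bmi,F,2,16.2
mean_bmi,F,5,15.3
mean_bmi,F,10,17.8
mean_bmi,F,15,20.8
mean_bmi,F,18,22.0
mean_bmi,F,30,26.0
mean_bmi,F,60,28.5
mean_bmi,F,99,27.0
hematocrit,M,0,0.47
hematocrit,M,1,0.37
hematocrit,M,12,0.40
hematocrit,M,18,0.45
hematocrit,M,99,0.45
hematocrit,F,0,0.47
hematocrit,F,1,0.37
hematocrit,F,12,0.39
hematocrit,F,18,0.40
hematocrit,F,99,0.40
fat_base,M,0,0.15
fat_base,M,18,0.15
fat_base,M,99,0.18
fat_base,F,0,0.15
fat_base,F,12,0.18
fat_base,F,18,0.25
fat_base,F,99,0.27
bv_per_kg,M,0,0.085
bv_per_kg,M,1,0.080
bv_per_kg,M,17,0.075
bv_per_kg,F,0,0.085
bv_per_kg,F,1,0.078
bv_per_kg,F,17,0.070
height_cv,M,,0.045
height_cv,F,,0.045
bmi_sigma,M,,0.16
bmi_sigma,F,,0.16
co_coeff,M,,12.0
co_coeff,F,,11.9
br_per_co,M,,0.048
br_per_co,F,,0.044
muscle_lean_frac,M,,0.45
muscle_lean_frac,F,,0.40
liver_lean_frac,M,,0.031
liver_lean_frac,F,,0.031
kidney_lean_frac,M,,0.0057
kidney_lean_frac,F,,0.0057
lung_lean_frac,M,,0.012
lung_lean_frac,F,,0.012
brain_per_kg,M,,0.085
brain_per_kg,F,,0.085
brain_max_l,M,,1.45
brain_max_l,F,,1.30
fat_slope_per_bmi,M,,0.016
fat_slope_per_bmi,F,,0.016
fat_min,M,,0.05
fat_min,F,,0.05
fat_max,M,,0.50
fat_max,F,,0.50
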