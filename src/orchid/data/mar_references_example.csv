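nutrient_id,sex,age_band,rda
protein_g,M,60+,57.9
protein_g,F,60+,48.8
fiber_g,M,60+,19.5
fiber_g,F,60+,16.5
vitamin_a_ug,M,60+,695.0
vitamin_a_ug,F,60+,586.0
thiamin_mg,M,60+,1.16
thiamin_mg,F,60+,0.976
riboflavin_mg,M,60+,1.39
riboflavin_mg,F,60+,1.17
niacin_mg,M,60+,13.9
niacin_mg,F,60+,11.7
vitamin_b6_mg,M,60+,1.39
vitamin_b6_mg,F,60+,1.17
folate_ug,M,60+,290.0
folate_ug,F,60+,244.0
vitamin_b12_ug,M,60+,3.48
vitamin_b12_ug,F,60+,2.93
vitamin_c_mg,M,60+,92.7
vitamin_c_mg,F,60+,78.1
vitamin_d_ug,M,60+,3.48
vitamin_d_ug,F,60+,2.93
vitamin_e_mg,M,60+,11.6
vitamin_e_mg,F,60+,9.76
calcium_mg,M,60+,927.0
calcium_mg,F,60+,781.0
magnesium_mg,M,60+,290.0
magnesium_mg,F,60+,244.0
iron_mg,M,60+,11.6
iron_mg,F,60+,9.76
zinc_mg,M,60+,9.27
zinc_mg,F,60+,7.81
potassium_mg,M,60+,2900.0
potassium_mg,F,60+,2440.0
copper_mg,M,60+,1.39
copper_mg,F,60+,1.17
selenium_ug,M,60+,58.0
selenium_ug,F,60+,48.8
iodine_ug,M,60+,116.0
iodine_ug,F,60+,97.6
phosphorus_mg,M,60+,1040.0
phosphorus_mg,F,60+,879.0
manganese_mg,M,60+,2.9
manganese_mg,F,60+,2.44
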