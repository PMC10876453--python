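nutrient_id,sex,age_band,ref,direction
protein_g,M,60+,51.8,at_least
protein_g,F,60+,43.9,at_least
fiber_g,M,60+,17.5,at_least
fiber_g,F,60+,14.8,at_least
alpha_linolenic_g,M,60+,1.19,at_least
alpha_linolenic_g,F,60+,1.01,at_least
vitamin_a_ug,M,60+,622.0,at_least
vitamin_a_ug,F,60+,527.0,at_least
thiamin_mg,M,60+,1.04,at_least
thiamin_mg,F,60+,0.879,at_least
riboflavin_mg,M,60+,1.24,at_least
riboflavin_mg,F,60+,1.05,at_least
niacin_mg,M,60+,12.4,at_least
niacin_mg,F,60+,10.5,at_least
vitamin_b6_mg,M,60+,1.24,at_least
vitamin_b6_mg,F,60+,1.05,at_least
folate_ug,M,60+,259.0,at_least
folate_ug,F,60+,220.0,at_least
vitamin_b12_ug,M,60+,3.11,at_least
vitamin_b12_ug,F,60+,2.64,at_least
vitamin_c_mg,M,60+,83.0,at_least
vitamin_c_mg,F,60+,70.3,at_least
vitamin_d_ug,M,60+,3.11,at_least
vitamin_d_ug,F,60+,2.64,at_least
vitamin_e_mg,M,60+,10.4,at_least
vitamin_e_mg,F,60+,8.79,at_least
calcium_mg,M,60+,830.0,at_least
calcium_mg,F,60+,703.0,at_least
magnesium_mg,M,60+,259.0,at_least
magnesium_mg,F,60+,220.0,at_least
iron_mg,M,60+,10.4,at_least
iron_mg,F,60+,8.79,at_least
zinc_mg,M,60+,8.3,at_least
zinc_mg,F,60+,7.03,at_least
potassium_mg,M,60+,2590.0,at_least
potassium_mg,F,60+,2200.0,at_least
copper_mg,M,60+,1.24,at_least
copper_mg,F,60+,1.05,at_least
selenium_ug,M,60+,51.9,at_least
selenium_ug,F,60+,43.9,at_least
iodine_ug,M,60+,104.0,at_least
iodine_ug,F,60+,87.9,at_least
phosphorus_mg,M,60+,933.0,at_least
phosphorus_mg,F,60+,791.0,at_least
manganese_mg,M,60+,2.59,at_least
manganese_mg,F,60+,2.2,at_least
sodium_mg,M,60+,1610.0,at_most
sodium_mg,F,60+,1420.0,at_most
free_sugars_g,M,60+,27.4,at_most
free_sugars_g,F,60+,24.1,at_most
saturated_fat_g,M,60+,29.4,at_most
saturated_fat_g,F,60+,25.8,at_most
cholesterol_mg,M,60+,247.0,at_most
cholesterol_mg,F,60+,217.0,at_most
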