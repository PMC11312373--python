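component,kind,max_points,std_max,std_zero,basis,column
total_fruits,adequacy,5,0.8,0.0,density,fruit_total_cup
whole_fruits,adequacy,5,0.4,0.0,density,fruit_whole_cup
total_vegetables,adequacy,5,1.1,0.0,density,veg_total_cup
greens_and_beans,adequacy,5,0.2,0.0,density,greens_beans_cup
whole_grains,adequacy,10,1.5,0.0,density,whole_grains_oz
dairy,adequacy,10,1.3,0.0,density,dairy_cup
total_protein_foods,adequacy,5,2.5,0.0,density,protein_oz
seafood_plant_proteins,adequacy,5,0.8,0.0,density,seafood_plant_oz
fatty_acids,adequacy,10,2.5,1.2,direct,fatty_acid_ratio
refined_grains,moderation,10,1.8,4.3,density,refined_grains_oz
sodium,moderation,10,1.1,2.0,density,sodium_g
added_sugars,moderation,10,6.5,26.0,direct,added_sugar_pct_energy
saturated_fats,moderation,10,8.0,16.0,direct,sat_fat_pct_energy
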