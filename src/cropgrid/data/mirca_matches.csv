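gaez_crop,mirca_crops,one_to_one,removal_order
Banana,Others_perennial,0,3
Barley,Barley,1,18
Cassava,Cassava,1,11
Cotton,Cotton,1,4
Crops_NES,Others_perennial;Others_annual,0,2
Fodder_crop,Fodder_grasses,0,2
Groundnut,Groundnut,1,6
Maize,Maize,1,20
Millet,Millet,1,16
Oil_palm_fruit,Oil_palm,1,8
Olives,Others_perennial,0,3
Other_cereals,Rye;Millet,0,17
Potato_&_Sweet_potato,Potatoes,1,12
Pulses,Pulses,1,5
Rapeseed,Canola,1,7
Rice,Rice,1,19
Sorghum,Sorghum,1,15
Soybean,Soybeans,1,14
Stimulants,Others_annual,0,1
Sugarbeet,Sugarbeet,1,9
Sugarcane,Sugarcane,1,10
Sunflower,Sunflower,1,13
Tobacco,Others_annual,0,1
Vegetables,Others_annual,0,1
Wheat,Wheat,1,21
Yams_and_other_roots,Others_annual,0,1
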