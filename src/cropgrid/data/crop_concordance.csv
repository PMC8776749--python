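faostat_code,faostat_name,gaez_crop,no_longer_reported
15,Wheat,Wheat,0
27,Rice_paddy,Rice,0
56,Maize,Maize,0
83,Sorghum,Sorghum,0
79,Millet,Millet,0
44,Barley,Barley,0
71,Rye,Other_cereals,0
75,Oats,Other_cereals,0
89,Buckwheat,Other_cereals,0
92,Quinoa,Other_cereals,0
94,Fonio,Other_cereals,0
97,Triticale,Other_cereals,0
101,Canary_seed,Other_cereals,0
103,Grain_mixed,Other_cereals,0
108,Cereals_nes,Other_cereals,0
116,Potatoes,Potato_&_Sweet_potato,0
122,Sweet_potatoes,Potato_&_Sweet_potato,0
125,Cassava,Cassava,0
135,Yautia_(cocoyam),Yams_and_other_roots,0
136,Taro_(cocoyam),Yams_and_other_roots,0
137,Yams,Yams_and_other_roots,0
149,Roots_and_tubers_nes,Yams_and_other_roots,0
157,Sugar_beet,Sugarbeet,0
156,Sugar_cane,Sugarcane,0
176,Beans_dry,Pulses,0
181,Broad_beans_dry,Pulses,0
187,Peas_dry,Pulses,0
191,Chick_peas,Pulses,0
195,Cow_peas_dry,Pulses,0
197,Pigeon_peas,Pulses,0
201,Lentils,Pulses,0
203,Bambara_beans,Pulses,0
211,Pulses_nes,Pulses,0
236,Soybeans,Soybean,0
270,Rapeseed,Rapeseed,0
267,Sunflower_seed,Sunflower,0
242,Groundnuts_with_shell,Groundnut,0
254,Oil_Palm_Fruit,Oil_palm_fruit,0
260,Olives,Olives,0
328,Seed_Cotton,Cotton,0
826,Tobacco_unmanufactured,Tobacco,0
486,Bananas,Banana,0
489,Plantains,Banana,0
656,Coffee_green,Stimulants,0
661,Cocoa_beans,Stimulants,0
667,Tea,Stimulants,0
671,Mate,Stimulants,0
358,Cabbages,Vegetables,0
366,Artichokes,Vegetables,0
367,Asparagus,Vegetables,0
372,Lettuce_and_chicory,Vegetables,0
373,Spinach,Vegetables,0
378,Cassave_Leaves,Vegetables,0
388,Tomatoes,Vegetables,0
393,Cauliflowers_and_broccoli,Vegetables,0
394,Pumpkins_squash_gourds,Vegetables,0
397,Cucumbers_and_gherkins,Vegetables,0
399,Eggplants_(aubergines),Vegetables,0
401,Chillies_peppers_green,Vegetables,0
402,Onions_shallots_green,Vegetables,0
403,Onions_dry,Vegetables,0
406,Garlic,Vegetables,0
407,Leeks,Vegetables,0
414,Beans_green,Vegetables,0
417,Peas_green,Vegetables,0
420,Vegetables_legum._nes,Vegetables,0
423,String_beans,Vegetables,0
426,Carrots_and_turnips,Vegetables,0
430,Okra,Vegetables,0
446,Maize_green,Vegetables,0
449,Mushrooms_and_truffles,Vegetables,0
459,Chicory_roots,Vegetables,0
461,Carobs,Vegetables,0
463,Vegetables_fresh_nes,Vegetables,0
689,Chillies_and_peppers_dry,Vegetables,0
216,Brazil_nuts_with_shell,Crops_NES,0
217,Cashew_nuts_with_shell,Crops_NES,0
220,Chestnut,Crops_NES,0
221,Almonds_with_shell,Crops_NES,0
222,Walnuts_with_shell,Crops_NES,0
223,Pistachios,Crops_NES,0
224,Kola_nuts,Crops_NES,0
225,Hazelnuts_with_shell,Crops_NES,0
226,Areca_nuts,Crops_NES,0
234,Nuts_nes,Crops_NES,0
249,Coconuts,Crops_NES,0
263,Karite_nuts_(sheanuts),Crops_NES,0
275,Tung_nuts,Crops_NES,0
299,Melonseed,Crops_NES,0
310,Kapok_Fruit,Crops_NES,0
490,Oranges,Crops_NES,0
495,Tangerines,Crops_NES,0
497,Lemons_and_limes,Crops_NES,0
507,Grapefruit_(incl._pomelos),Crops_NES,0
512,Fruit_citrus_nes,Crops_NES,0
515,Apples,Crops_NES,0
521,Pears,Crops_NES,0
523,Quinces,Crops_NES,0
526,Apricots,Crops_NES,0
530,Cherries_sour,Crops_NES,0
531,Cherries,Crops_NES,0
534,Peaches_and_nectarines,Crops_NES,0
536,Plums_and_sloes,Crops_NES,0
541,Fruit_stone_nes,Crops_NES,0
542,Fruit_pome_nes,Crops_NES,0
544,Strawberries,Crops_NES,0
547,Raspberries,Crops_NES,0
549,Gooseberries,Crops_NES,0
550,Currants,Crops_NES,0
552,Blueberries,Crops_NES,0
554,Cranberries,Crops_NES,0
558,Berries_nes,Crops_NES,0
560,Grapes,Crops_NES,0
567,Watermelons,Crops_NES,0
568,Melons_other,Crops_NES,0
569,Figs,Crops_NES,0
571,Mangoes_guavas,Crops_NES,0
572,Avocados,Crops_NES,0
574,Pineapples,Crops_NES,0
577,Dates,Crops_NES,0
587,Persimmons,Crops_NES,0
591,Cashewapple,Crops_NES,0
592,Kiwi_fruit,Crops_NES,0
600,Papayas,Crops_NES,0
603,Fruit_tropical_fresh_nes,Crops_NES,0
619,Fruit_fresh_nes,Crops_NES,0
161,Sugar_crops_nes,Crops_NES,0
205,Vetches,Crops_NES,0
210,Lupins,Crops_NES,0
265,Castor_oil_seed,Crops_NES,0
277,Jojoba_Seeds,Crops_NES,0
280,Safflower_seed,Crops_NES,0
289,Sesame_seed,Crops_NES,0
292,Mustard_seed,Crops_NES,0
296,Poppy_seed,Crops_NES,0
305,Tallowtree_Seeds,Crops_NES,0
333,Linseed,Crops_NES,0
336,Hempseed,Crops_NES,0
339,Oilseeds_nes,Crops_NES,0
677,Hops,Crops_NES,0
687,Pepper_(piper_spp.),Crops_NES,0
692,Vanilla,Crops_NES,0
693,Cinnamon_(canella),Crops_NES,0
698,Cloves,Crops_NES,0
702,Nutmeg_mace_cardamoms,Crops_NES,0
711,Anise_badian_fennel,Crops_NES,0
720,Ginger,Crops_NES,0
723,Spices_nes,Crops_NES,0
748,Peppermint,Crops_NES,0
754,Pyrethrum_dried,Crops_NES,0
773,Flax_fibre_and_tow,Crops_NES,0
777,Hemp_tow_waste,Crops_NES,0
780,Jute,Crops_NES,0
782,Bastfibres_other,Crops_NES,0
788,Ramie,Crops_NES,0
789,Sisal,Crops_NES,0
800,Agave_fibres_nes,Crops_NES,0
809,Manila_fibre_(abaca),Crops_NES,0
821,Fibre_crops_nes,Crops_NES,0
644,Cabbages_for_fodder,Fodder_crop,1
645,Pumpkins_for_fodder,Fodder_crop,1
646,Turnips_for_fodder,Fodder_crop,1
647,Beets_for_fodder,Fodder_crop,1
648,Carrots_for_fodder,Fodder_crop,1
649,Swedes_for_fodder,Fodder_crop,1
655,Vegetables_&_roots_fodder,Fodder_crop,1
651,Forage_products,Fodder_crop,1
636,Forage_&_silage_maize,Fodder_crop,1
637,Forage_&_silage_sorghum,Fodder_crop,1
638,Forage_&_silage_rye_grass,Fodder_crop,1
639,Forage_&_silage_grasses_nes,Fodder_crop,1
640,Forage_&_silage_clover,Fodder_crop,1
641,Forage_&_silage_alfalfa,Fodder_crop,1
642,Forage_&_silage_green_oilsd,Fodder_crop,1
643,Forage_&_silage_legumes,Fodder_crop,1
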