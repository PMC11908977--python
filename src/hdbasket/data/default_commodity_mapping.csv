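commodity_code,commodity_name,display_aggregate,group
2511,Wheat and products,wheat,starchy_staples
2805,Rice and products,rice,starchy_staples
2513,Barley and products,other cereals,starchy_staples
2514,Maize and products,maize,starchy_staples
2515,Rye and products,other cereals,starchy_staples
2516,Oats,other cereals,starchy_staples
2517,Millet and products,other cereals,starchy_staples
2518,Sorghum and products,other cereals,starchy_staples
2520,"Cereals, other",other cereals,starchy_staples
2531,Potatoes and products,potatoes,starchy_staples
2532,Cassava and products,cassava,starchy_staples
2533,Sweet potatoes,other roots,starchy_staples
2534,"Roots, other",other roots,starchy_staples
2535,Yams,other roots,starchy_staples
2616,Plantains,plantains,starchy_staples
2615,Bananas,bananas,fruits
2611,"Oranges, mandarines",citrus,fruits
2612,"Lemons, limes and products",citrus,fruits
2613,Grapefruit and products,citrus,fruits
2614,"Citrus, other",citrus,fruits
2617,Apples and products,apples,fruits
2618,Pineapples and products,other fruits,fruits
2619,Dates,other fruits,fruits
2620,Grapes and products (excl wine),grapes,fruits
2625,"Fruits, other",other fruits,fruits
2601,Tomatoes and products,tomatoes,vegetables
2602,Onions,onions,vegetables
2605,"Vegetables, other",other vegetables,vegetables
2731,Bovine meat,red meat,animal_source_foods
2732,Mutton & goat meat,red meat,animal_source_foods
2733,Pigmeat,pork,animal_source_foods
2734,Poultry meat,poultry,animal_source_foods
2735,"Meat, other",other meat,animal_source_foods
2736,Offals edible,other meat,animal_source_foods
2744,Eggs,eggs,animal_source_foods
2848,Milk - excluding butter,milk,animal_source_foods
2761,Freshwater fish,freshwater fish,animal_source_foods
2762,Demersal fish,other marine fish,animal_source_foods
2763,Pelagic fish,other marine fish,animal_source_foods
2764,"Marine fish, other",other marine fish,animal_source_foods
2765,Crustaceans,shellfish,animal_source_foods
2766,Cephalopods,shellfish,animal_source_foods
2767,"Molluscs, other",shellfish,animal_source_foods
2546,Beans,beans,legumes_nuts_seeds
2547,Peas,other pulses and seeds,legumes_nuts_seeds
2549,"Pulses, other and products",other pulses and seeds,legumes_nuts_seeds
2551,Nuts and products,tree nuts,legumes_nuts_seeds
2555,Soyabeans,soyabeans,legumes_nuts_seeds
2556,Groundnuts,groundnuts,legumes_nuts_seeds
2557,Sunflower seed,other pulses and seeds,legumes_nuts_seeds
2560,Coconuts - incl copra,coconuts,legumes_nuts_seeds
2561,Sesame seed,other pulses and seeds,legumes_nuts_seeds
2563,Olives (including preserved),olives,legumes_nuts_seeds
2571,Soyabean oil,soybean oil,oils_fats
2572,Groundnut oil,other vegetable oils,oils_fats
2573,Sunflowerseed oil,sunflower oil,oils_fats
2574,Rape and mustard oil,rape and mustard oil,oils_fats
2575,Cottonseed oil,other vegetable oils,oils_fats
2576,Palmkernel oil,palm oil,oils_fats
2577,Palm oil,palm oil,oils_fats
2579,Sesameseed oil,other vegetable oils,oils_fats
2580,Olive oil,olive oil,oils_fats
2586,"Oilcrops oil, other",other vegetable oils,oils_fats
2737,"Fats, animals, raw",animal fats,oils_fats
2740,Butter and ghee,animal fats,oils_fats
2743,Cream,animal fats,oils_fats
2542,Sugar (raw equivalent),sugar,SUGAR
2543,"Sweeteners, other",other sweeteners,SUGAR
2745,Honey,other sweeteners,SUGAR
2630,Coffee and products,stimulants,EXCLUDED
2635,Tea (including mate),stimulants,EXCLUDED
2633,Cocoa beans and products,stimulants,EXCLUDED
2640,Pepper,spices,EXCLUDED
2641,Pimento,spices,EXCLUDED
2642,Cloves,spices,EXCLUDED
2645,"Spices, other",spices,EXCLUDED
2655,Wine,alcoholic beverages,EXCLUDED
2656,Beer,alcoholic beverages,EXCLUDED
2657,"Beverages, fermented",alcoholic beverages,EXCLUDED
2658,"Beverages, alcoholic",alcoholic beverages,EXCLUDED
2680,Infant food,infant food,EXCLUDED
2775,Aquatic plants,aquatic plants,EXCLUDED
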