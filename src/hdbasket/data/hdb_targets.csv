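group,kcal
starchy_staples,1160
fruits,160
vegetables,110
animal_source_foods,300
legumes_nuts_seeds,300
oils_fats,300
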