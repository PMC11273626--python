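product,category,content_mg_per_g,daily_amount_g,body_weight_kg
example_supplement,food_supplement,1.0,5.0,60.0
example_medicine,herbal_medicine,2.0,6.0,60.0
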