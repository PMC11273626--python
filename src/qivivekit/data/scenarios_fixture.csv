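# Editable test fixture: rows calibrated so the supplement EDIs span
# 0.00017-0.68 mg/kg/day and the medicinal EDIs span 0.0005-1.9 mg/kg/day
# at a 60 kg body weight.
product,category,content_mg_per_g,daily_amount_g,body_weight_kg
supplement_low,food_supplement,0.0017,6.0,60.0
supplement_mid_a,food_supplement,0.5,3.0,60.0
supplement_mid_b,food_supplement,1.2,5.0,60.0
supplement_high,food_supplement,4.08,10.0,60.0
medicine_low,herbal_medicine,0.01,3.0,60.0
medicine_mid,herbal_medicine,3.0,6.0,60.0
medicine_high,herbal_medicine,22.8,5.0,60.0
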