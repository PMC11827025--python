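nutrient,amount,unit
protein,6.3,g
choline,147.0,mg
vitamin_d,1.1,ug
selenium,15.4,ug
vitamin_b2,0.26,mg
vitamin_a,75.0,ug
folate,22.0,ug
vitamin_b12,0.55,ug
iron,0.6,mg
zinc,0.53,mg
calcium,25.0,mg
magnesium,5.0,mg
potassium,63.0,mg
vitamin_e,0.52,mg
vitamin_b1,0.03,mg
vitamin_b6,0.06,mg
vitamin_b3,0.03,mg
vitamin_c,0.0,mg
lutein_zeaxanthin,176.0,ug
dha,19.0,mg
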