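nutrient,sex,ear,ai,rda,unit
calcium,female,1100,,1300,mg
calcium,male,1100,,1300,mg
choline,female,,475,,mg
choline,male,,475,,mg
folate,female,330,,400,ug
folate,male,330,,400,ug
iron,female,7.9,,15,mg
iron,male,7.7,,11,mg
magnesium,female,300,,360,mg
magnesium,male,340,,410,mg
potassium,female,,2300,,mg
potassium,male,,3000,,mg
selenium,female,45,,55,ug
selenium,male,45,,55,ug
vitamin_a,female,485,,700,ug
vitamin_a,male,630,,900,ug
vitamin_b1,female,0.9,,1.0,mg
vitamin_b1,male,1.0,,1.2,mg
vitamin_b2,female,0.9,,1.0,mg
vitamin_b2,male,1.1,,1.3,mg
vitamin_b3,female,11,,14,mg
vitamin_b3,male,12,,16,mg
vitamin_b6,female,1.0,,1.2,mg
vitamin_b6,male,1.1,,1.3,mg
vitamin_b12,female,2.0,,2.4,ug
vitamin_b12,male,2.0,,2.4,ug
vitamin_c,female,56,,65,mg
vitamin_c,male,63,,75,mg
vitamin_d,female,10,,15,ug
vitamin_d,male,10,,15,ug
vitamin_e,female,12,,15,mg
vitamin_e,male,12,,15,mg
zinc,female,7.3,,9,mg
zinc,male,8.5,,11,mg
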