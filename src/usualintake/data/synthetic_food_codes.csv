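food_code,description,role
25021110,"Egg, whole, boiled",primary
25020310,"Egg omelet or scrambled egg, made without fat",primary
25021010,"Egg, whole, fried",primary
25021500,"Egg substitute, omelet",substitute
25022000,"Duck egg, whole, cooked",substitute
25022110,"Quail egg, canned",substitute
58100110,"Burrito with egg",ingredient
27510110,"Egg sandwich on bun",ingredient
53420000,"Pastry, danish",ingredient
51101010,"Bread, white, enriched",ingredient
11111000,"Milk, whole",none
63101000,"Apple, raw",none
58106210,"Pizza, cheese",none
24102010,"Chicken breast, grilled",none
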