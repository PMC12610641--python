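compound,threshold,medium,source,odors
1-Hexanol,0.74,air,threshold compilation,"Almond, apple, banana, bread, cut grass"
α-Pinene,7.9,air,threshold compilation,"Berry, citrus, floral, fruit, lemon"
Sabinene,2,air,threshold compilation,"Citrus, green, herb, pepper, spice"
β-Pinene,0.14,water,threshold compilation,"Woody, terpentine"
β-Myrcene,0.061,air,threshold compilation,"Balsamic, fruit, geranium, green, herb"
Butyl butanoate,0.028,air,threshold compilation,Floral
α-Terpinene,7.9,air,threshold compilation,"Berry, citrus, floral, fruit, lemon"
P-Cymene,7.2,air,threshold compilation,"Citrus, fresh, fruit, gasoline, lemon"
D-Limonene,0.045,air,threshold compilation,"Citrus, fresh, lemon, mint, orange"
β-Phellandrene,0.5,air,threshold compilation,"Mint, spice, terpentine"
β-Ocimene,0.034,water,threshold compilation,"Herb, sweet"
γ-Terpinene,37.5,air,threshold compilation,"Bitter, caramel, citrus, fruit, gasoline"
Terpinolene,0.2,air,threshold compilation,"Citrus, floral, herb, pine, plastic"
Linalool,0.013,air,threshold compilation,"Bergamot, coriander, floral, flower, grape"
Nonanal,0.23,air,threshold compilation,"Aldehyde, beany, citrus, cucumber, fat"
Terpinen-4-ol,0.59,air,threshold compilation,"Citrus, earth, floral, herb, must"
Butyl caproate,0.7,air,threshold compilation,"Fruit, grass, green"
α-Terpineol,0.41,air,threshold compilation,"Anise, citrus, floral, fresh, lily"
β-Caryophyllene,1.5,air,threshold compilation,"Candy, citrus, clove, fried, green"
Humulene,0.16,water,threshold compilation,"Balsamic, carrot, hop, resin, soap"
Elemol,0.1,air,threshold compilation,"Green, wood"
E-Nerolidol,1.25,water,threshold compilation,"Fir, linoleum, pine"
Caryophyllene oxide,2.4,air,threshold compilation,"Citrus, fruit, herb, must, spice"
γ-Dodecalactone,0.00481,air,threshold compilation,"Apricot, flower, fruit, peach, sweet"
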