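attribute,reference,definition
citrus,0.01% D-Limonene in PG,"Fresh, peel-like zest reminiscent of lemon or orange."
minty,0.01% L-Menthol in water,"Cooling, herbal note with a refreshing sensation."
woody,0.1% Cedrol in PG,"Resinous, bark-like aroma evoking pine or sandalwood."
floral,0.02% Linalool in PG,"Sweet, blossom-like scent similar to rose or jasmine."
coconut-milk,Coconut juice,"Creamy, lactonic sweetness akin to coconut or peach."
herbal,"0.05% 1,8-Cineole in PG","Green, medicinal character reminiscent of eucalyptus or grass."
spicy,0.02% eugenol in PG,"Pungent, warm note suggestive of pepper or clove."
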