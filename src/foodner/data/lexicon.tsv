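# Fixture lexicon: lemma<TAB>TAG[;TAG...] with tags in bracket notation CODE[Label].
# A small, hand-curated stand-in for a full Hansard/USAS-style token-level tag
# resource; synthetic in coverage, but faithful in format and in the codes it
# assigns to the worked examples it contains.
grilled	AG.01.t.07[Cooking]
chicken	AG.01.d.06[Fowls]
tortilla	AG.01.n.12[Pancake/tortilla/oatcake]
chips	AG.01.n.11[Bread]
dry	AG.01.m[Substances for food preparation]
ranch	AG.01.h.02[Vegetables]
salad	AG.01.h.02[Vegetables]
dressing	AG.01.n.09[Prepared vegetables and dishes]
mix	AG.01.m[Substances for food preparation]
cauliflower	AG.01.h.02.d[Cabbage/kale]
water	AG.01[Food]
mixture	AG.01.af[Tea manufacture];AG.01.m[Substances for food preparation]
mashed	AG.01.ae.03[Brewing];AG.01.t.11[Pulping]
potato	AG.01.h.02.c[Potato]
cream	AG.01.e[Dairy products]
tartar	AG.01.m[Substances for food preparation]
passion	AG.01.h.01[Fruit]
fruit	AG.01.h.01[Fruit]
juice	AG.01.f.03[Juice]
cinnamon	AG.01.l.03[Spice]
stick	AG.01.l.03[Spice]
soda	AG.01.f.05[Soft drink]
club	AG.01.f.05[Soft drink]
kefir	AG.01.e[Dairy products]
milk	AG.01.e[Dairy products]
butter	AG.01.e.01[Butter]
cheese	AG.01.e.02[Cheese]
egg	AG.01.g[Eggs]
flour	AG.01.k[Flour]
sugar	AG.01.l.02[Sweetener (syrup/honey/chocolate)]
honey	AG.01.l.02[Sweetener (syrup/honey/chocolate)]
chocolate	AG.01.l.02[Sweetener (syrup/honey/chocolate)]
bread	AG.01.n.11[Bread]
onion	AG.01.h.02.e[Onion/leek/garlic]
garlic	AG.01.h.02.e[Onion/leek/garlic]
beef	AG.01.d.02[Beef]
pork	AG.01.d.03[Pork]
salmon	AG.01.d.09[Fish]
rice	AG.01.k.02[Rice]
pepper	AG.01.l.03[Spice]
jalapeno	AG.01.h.02[Vegetables]
tomato	AG.01.h.02[Vegetables]
lemon	AG.01.h.01[Fruit]
vanilla	AG.01.l.03[Spice]
coffee	AG.01.f.04[Coffee]
tea	AG.01.f.06[Tea]
salt	AG.01.l.01[Salt]
oil	AG.01.m.02[Oil]
vinegar	AG.01.m[Substances for food preparation]
yeast	AG.01.m[Substances for food preparation]
venison	AE.07[Deer]
rabbit	AE.05[Rabbits]
dandelion	AF.11[Herbs/weeds]
elderflower	AF.09[Flowers]
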