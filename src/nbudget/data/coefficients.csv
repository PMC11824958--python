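item,category,basis,protein_fraction,n_fraction,density_kg_per_m3,note
Wheat,food-plant,mass-protein,0.126,,,synthetic registry; whole-grain bread wheat
Barley,food-plant,mass-protein,0.124,,,synthetic registry
Potatoes,food-plant,mass-protein,0.020,,,synthetic registry; fresh weight
Pulses,food-plant,mass-protein,0.240,,,synthetic registry; dry pulses
Milk,dairy-egg,mass-protein,0.034,,,synthetic registry; whole cow milk
Eggs,dairy-egg,mass-protein,0.126,,,synthetic registry
Bovine meat,food-animal-agriculture,mass-protein,0.180,,,synthetic registry; dressed meat
Pig meat,food-animal-agriculture,mass-protein,0.180,,,synthetic registry; dressed meat
Poultry meat,food-animal-agriculture,mass-protein,0.180,,,synthetic registry; dressed meat
Salmon,food-fisheries,mass-fresh,,0.030,,synthetic registry; farmed Atlantic salmon on usable weight
Trout,food-fisheries,mass-fresh,,0.030,,synthetic registry
Cod,food-fisheries,mass-fresh,,0.029,,synthetic registry
Herring,food-fisheries,mass-fresh,,0.029,,synthetic registry
Crustaceans,food-fisheries,mass-fresh,,0.028,,synthetic registry
Hay,feed-forage,mass-protein,0.085,,,synthetic registry; timothy hay
Silage,feed-forage,mass-protein,0.040,,,synthetic registry
Gluten feed and meal,feed-nonforage,mass-protein,0.250,,,synthetic registry
Soya bean cake,seed-cake,mass-protein,0.450,,,synthetic registry; cold-pressed cake
Rape and mustard cake,seed-cake,mass-protein,0.330,,,synthetic registry; cold-pressed cake
Sunflower seed cake,seed-cake,mass-protein,0.290,,,synthetic registry; cold-pressed cake
Wool,fibre,mass-protein,0.970,,,synthetic registry; keratin-dominated
Industrial roundwood coniferous,wood-conifer,volume-wood,,0.0014,400,dry-wood N on basic density
Industrial roundwood non-coniferous,wood-nonconifer,volume-wood,,0.0017,500,dry-wood N on basic density
Wood fuel,wood-conifer,volume-wood,,0.0014,400,conifer characteristics assumed
Wood pulp,pulp,mass-fraction,,0.0,,N removed during pulping
Paper and paperboard,paper,mass-fraction,,0.0,,negligible N after pulping
Fertilizer N,fertilizer-N,mass-N-direct,,1.0,,quantity already reported as N
Petroleum,petroleum,mass-fossil,,0.004,,continental-shelf crude average
Bituminous coal,coal-bituminous,mass-fossil,,0.020,,high-grade coal
Metallurgical coke,coke,mass-fossil,,0.020,,production only; trade counts 0
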