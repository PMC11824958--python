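source,sink,n_gg,label,year,note
atmosphere,non-managed land,92.8,natural inputs to non-managed land,2018,deposition + biological fixation + rock weathering allocation
atmosphere,forest,61.2,natural inputs to forest,2018,deposition + biological fixation + rock weathering allocation
atmosphere,agricultural land,22.2,natural inputs to agricultural land,2018,deposition + biological fixation + rock weathering allocation
industry,agricultural land,102.4,synthetic fertilizer use,2018,domestic agricultural use of synthetic N fertilizer
industry,rest-of-world,554.2,synthetic fertilizer export,2018,largest single commodity N export
industry,people & settlements,133.19,petroleum domestic consumption,2018,
industry,rest-of-world,229.54,petroleum export,2018,
rest-of-world,industry,0.01266,coal net import,2018,12.66 Mg N
industry,people & settlements,0.01567,coal domestic use,2018,15.67 Mg N of produced coal used domestically
forest,people & settlements,437.49,industrial logs domestic use,2018,
forest,rest-of-world,202.40,industrial logs export,2018,
forest,people & settlements,106.74,other forestry products domestic use,2018,
forest,rest-of-world,176.84,other forestry products export,2018,
forest,atmosphere,20.1,denitrification,2018,soil-covered area x 0.57 kg N/ha/yr
rest-of-world,fisheries & coastal waters,124.0,aquaculture feed import,2018,salmon and trout feed protein x Jones factor
rest-of-world,fisheries & coastal waters,48.8,fisheries products import,2018,
fisheries & coastal waters,people & settlements,68.6,fisheries products domestic supply,2018,
fisheries & coastal waters,rest-of-world,112.7,fisheries products export,2018,assigned entirely to domestic capture and aquaculture
people & settlements,livestock,80.25,food-category feed,2018,food-category items diverted to animal feed
rest-of-world,livestock,4.17,imported feed,2018,seed cake and gluten
rest-of-world,livestock,16.62,non-food feed import,2018,
agricultural land,livestock,31.67,non-food feed domestic,2018,
agricultural land,livestock,31.46,forage feed,2018,hay and grazing
livestock,people & settlements,28.54,animal products,2018,N retained in animals and animal products used as food
livestock,rest-of-world,0.314,animal product export,2018,
rest-of-world,livestock,0.0065,live animal import,2018,6.5 Mg N
livestock,rest-of-world,0.0028,live animal export,2018,2.8 Mg N
livestock,agricultural land,49.27,manure left on pasture,2018,
livestock,agricultural land,48.22,manure applied to cropland,2018,
agricultural land,hydrosphere,29.25,manure leaching,2018,
agricultural land,atmosphere,19.50,manure volatilization,2018,ammonia
people & settlements,atmosphere,0.33,breath and skin ammonia,2018,
people & settlements,hydrosphere,19.4,sewage dissolved discharge,2018,
people & settlements,atmosphere,6.21,sewage volatile loss,2018,
people & settlements,agricultural land,2.3,sewage sludge to soils,2018,
people & settlements,agricultural land,28.3,biowaste to soils,2018,
rest-of-world,people & settlements,0.027,net migration,2018,18103 people at 75 kg mean live weight
people & settlements,atmosphere,76.64,NOx transport,2018,
industry,atmosphere,50.97,NOx energy exploration and industry,2018,
industry,atmosphere,1.89,NOx energy generation,2018,
people & settlements,atmosphere,1.29,NOx heating,2018,
people & settlements,atmosphere,0.148,NOx other,2018,
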