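ecosystem,area_km2,censored
Boreal heath barrens,9.0,False
Coastal oak-beech forest,2.8,False
Coastal oak-heath forest,19.8,False
Coastal oak-hickory forest,6.3,False
Coastal oak-holly forest,1.3,False
Coastal oak-laurel forest,1.3,False
Dwarf pine plains,5.6,False
Great Lakes dunes,2.9,False
Hempstead Plains grassland,0.0,True
Maritime beach,10.8,False
Maritime beech forest,0.3,False
Maritime dunes,9.3,False
Maritime freshwater interdunal swales,1.3,False
Maritime grassland,0.6,False
Maritime heathland,1.7,False
Maritime holly forest,0.0,True
Maritime oak forest,3.5,False
Maritime pitch pine dune woodland,3.1,False
Maritime red cedar forest,0.3,False
Maritime shrubland,4.1,False
Pitch pine-heath barrens,16.4,False
Pitch pine-oak forest,133.2,False
Pitch pine-oak-heath woodland,50.1,False
Pitch pine-scrub oak barrens,37.8,False
Successional blueberry heath,11.2,False
Successional maritime forest,2.4,False
Successional northern sandplain grassland,17.2,False
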