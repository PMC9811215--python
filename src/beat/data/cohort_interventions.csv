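country,zone,category_id,planned,realized
NL,green,purchased_animals,0,0
NL,green,bedding_materials,0,0
NL,green,contaminated_feed,0,0
NL,green,drinking_water,1,1
NL,green,thinning,2,1
NL,green,depopulation,0,0
NL,green,consecutive_flocks,2,2
NL,green,between_houses,3,3
NL,green,dead_bird_removal,5,3
NL,green,rodents_insects_green,2,1
NL,green,wild_birds_green,0,0
NL,green,outdoor_areas,0,0
NL,green,cd_entry_room,0,0
NL,green,cd_broiler_house,1,1
NL,orange_green,og_personnel_access,22,19
NL,orange_green,og_material_access,0,0
NL,orange_green,og_wild_birds,0,0
NL,orange,house_position,2,2
NL,orange,cadaver_storage,0,0
NL,orange,manure_storage,0,0
NL,orange,feed_storage,2,2
NL,orange,bedding_storage,1,0
NL,orange,other_poultry,0,0
NL,orange,other_farm_animals,0,0
NL,orange,rodents_insects_orange,0,0
NL,orange,wild_birds_orange,0,0
NL,orange,yard_surfaces,0,0
NL,orange,cd_farm_yard,2,2
NL,red_orange,ro_personnel_access,11,7
NL,red_orange,ro_transport_vehicles,4,4
NL,red_orange,ro_wild_birds,2,1
NL,red_orange,ro_fence_separation,3,2
NL,red_orange,ro_arrival_sign,4,2
NL,red_orange,ro_visitor_registration,1,1
NL,red,poultry_density,0,0
NL,red,nearest_poultry_farm,0,0
NL,red,public_road_distance,0,0
NL,red,poultry_litter_spread,0,0
NL,red,other_litter_spread,0,0
NL,red,mowing,1,1
NL,red,ploughing,0,0
NL,red,water_ponds,0,0
NL,red,migratory_birds,0,0
NL,red,pest_pressure,0,0
NL,red,parking_red,4,3
NL,red,dirty_clean_separation,2,1
CY,green,purchased_animals,7,7
CY,green,bedding_materials,0,0
CY,green,contaminated_feed,7,0
CY,green,drinking_water,21,19
CY,green,thinning,14,0
CY,green,depopulation,0,0
CY,green,consecutive_flocks,7,2
CY,green,between_houses,7,0
CY,green,dead_bird_removal,7,1
CY,green,rodents_insects_green,0,0
CY,green,wild_birds_green,7,2
CY,green,outdoor_areas,0,0
CY,green,cd_entry_room,0,0
CY,green,cd_broiler_house,0,0
CY,orange_green,og_personnel_access,35,10
CY,orange_green,og_material_access,0,0
CY,orange_green,og_wild_birds,0,0
CY,orange,house_position,7,0
CY,orange,cadaver_storage,0,0
CY,orange,manure_storage,0,0
CY,orange,feed_storage,7,0
CY,orange,bedding_storage,0,0
CY,orange,other_poultry,0,0
CY,orange,other_farm_animals,0,0
CY,orange,rodents_insects_orange,0,0
CY,orange,wild_birds_orange,0,0
CY,orange,yard_surfaces,0,0
CY,orange,cd_farm_yard,7,0
CY,red_orange,ro_personnel_access,7,2
CY,red_orange,ro_transport_vehicles,7,2
CY,red_orange,ro_wild_birds,0,0
CY,red_orange,ro_fence_separation,7,4
CY,red_orange,ro_arrival_sign,0,0
CY,red_orange,ro_visitor_registration,7,5
CY,red,poultry_density,0,0
CY,red,nearest_poultry_farm,0,0
CY,red,public_road_distance,0,0
CY,red,poultry_litter_spread,0,0
CY,red,other_litter_spread,0,0
CY,red,mowing,0,0
CY,red,ploughing,0,0
CY,red,water_ponds,0,0
CY,red,migratory_birds,0,0
CY,red,pest_pressure,0,0
CY,red,parking_red,0,0
CY,red,dirty_clean_separation,7,7
GR,green,purchased_animals,15,0
GR,green,bedding_materials,0,0
GR,green,contaminated_feed,15,0
GR,green,drinking_water,60,30
GR,green,thinning,45,0
GR,green,depopulation,0,0
GR,green,consecutive_flocks,15,0
GR,green,between_houses,15,0
GR,green,dead_bird_removal,0,0
GR,green,rodents_insects_green,0,0
GR,green,wild_birds_green,0,0
GR,green,outdoor_areas,0,0
GR,green,cd_entry_room,15,15
GR,green,cd_broiler_house,30,0
GR,orange_green,og_personnel_access,60,45
GR,orange_green,og_material_access,0,0
GR,orange_green,og_wild_birds,0,0
GR,orange,house_position,15,0
GR,orange,cadaver_storage,0,0
GR,orange,manure_storage,0,0
GR,orange,feed_storage,15,0
GR,orange,bedding_storage,15,0
GR,orange,other_poultry,0,0
GR,orange,other_farm_animals,0,0
GR,orange,rodents_insects_orange,15,0
GR,orange,wild_birds_orange,15,0
GR,orange,yard_surfaces,0,0
GR,orange,cd_farm_yard,1,0
GR,red_orange,ro_personnel_access,6,0
GR,red_orange,ro_transport_vehicles,15,0
GR,red_orange,ro_wild_birds,0,0
GR,red_orange,ro_fence_separation,3,0
GR,red_orange,ro_arrival_sign,0,0
GR,red_orange,ro_visitor_registration,0,0
GR,red,poultry_density,0,0
GR,red,nearest_poultry_farm,2,0
GR,red,public_road_distance,0,0
GR,red,poultry_litter_spread,1,0
GR,red,other_litter_spread,0,0
GR,red,mowing,0,0
GR,red,ploughing,0,0
GR,red,water_ponds,0,0
GR,red,migratory_birds,0,0
GR,red,pest_pressure,0,0
GR,red,parking_red,0,0
GR,red,dirty_clean_separation,15,0
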