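zone,category_id,NL,CY,GR,overall
green,purchased_animals,0.65,0.66,0.13,0.43
green,bedding_materials,1.00,1.00,1.00,1.00
green,contaminated_feed,0.98,0.00,0.50,0.59
green,drinking_water,0.76,0.68,0.63,0.69
green,thinning,0.14,0.05,0.00,0.07
green,depopulation,0.18,0.08,0.00,0.09
green,consecutive_flocks,0.85,0.82,0.58,0.73
green,between_houses,0.57,0.67,0.87,0.71
green,dead_bird_removal,0.64,0.50,1.00,0.76
green,rodents_insects_green,0.93,0.89,1.00,0.95
green,wild_birds_green,0.93,0.29,0.20,0.50
green,outdoor_areas,0.42,1.00,0.60,0.61
green,cd_entry_room,0.80,0.35,1.00,0.80
green,cd_broiler_house,0.95,1.00,1.00,0.98
orange_green,og_personnel_access,0.65,0.21,0.75,0.61
orange_green,og_material_access,0.51,0.50,0.12,0.34
orange_green,og_wild_birds,0.64,0.72,0.62,0.65
orange,house_position,0.64,1.00,0.67,0.72
orange,cadaver_storage,0.96,0.50,0.50,0.68
orange,manure_storage,0.86,1.00,0.53,0.75
orange,feed_storage,0.75,0.50,0.50,0.60
orange,bedding_storage,0.79,1.00,0.00,0.50
orange,other_poultry,0.89,1.00,0.75,0.85
orange,other_farm_animals,0.63,1.00,0.72,0.74
orange,rodents_insects_orange,0.85,0.67,0.33,0.60
orange,wild_birds_orange,0.79,0.72,0.30,0.57
orange,yard_surfaces,0.96,0.71,0.00,0.51
orange,cd_farm_yard,0.68,0.22,0.49,0.51
red_orange,ro_personnel_access,0.53,0.53,0.74,0.62
red_orange,ro_transport_vehicles,0.38,0.64,0.02,0.28
red_orange,ro_wild_birds,0.74,0.67,0.64,0.69
red_orange,ro_fence_separation,0.79,0.57,0.07,0.44
red_orange,ro_arrival_sign,0.57,0.71,1.00,0.78
red_orange,ro_visitor_registration,0.86,0.00,1.00,0.75
red,poultry_density,0.79,0.29,0.13,0.42
red,nearest_poultry_farm,0.64,0.36,0.43,0.50
red,public_road_distance,0.30,0.57,0.13,0.28
red,poultry_litter_spread,0.80,1.00,0.56,0.74
red,other_litter_spread,0.26,0.04,0.71,0.40
red,mowing,0.23,0.21,0.50,0.34
red,ploughing,0.45,0.07,0.50,0.40
red,water_ponds,0.43,0.57,0.87,0.64
red,migratory_birds,0.71,0.71,0.93,0.81
red,pest_pressure,0.75,0.21,0.00,0.33
red,parking_red,0.43,1.00,1.00,0.78
red,dirty_clean_separation,0.29,0.48,0.33,0.34
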