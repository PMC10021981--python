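# Default OSM tag -> (layer, category, subcategory) mapping for the risk score.
#
# The layer decides which density surface a point of interest feeds:
# "obesogenic" features are hypothesised to raise obesity risk, "protective"
# features to lower it.  Subcategory names "supermarket" and "gym" are the ones
# the double-weighting scheme multiplies.  Users override this file entirely
# via `load_category_mapping(path)`.
entries:
  # --- obesogenic: unhealthy food environment ---
  - {tag: amenity=fast_food,        layer: obesogenic, category: Unhealthy_food, subcategory: Fast_food}
  - {tag: shop=pastry,              layer: obesogenic, category: Unhealthy_food, subcategory: Pastry}
  - {tag: shop=confectionery,       layer: obesogenic, category: Unhealthy_food, subcategory: Sweets}
  - {tag: shop=bakery,              layer: obesogenic, category: Unhealthy_food, subcategory: Pastry}
  - {tag: amenity=ice_cream,        layer: obesogenic, category: Unhealthy_food, subcategory: Sweets}
  - {tag: amenity=vending_machine,  layer: obesogenic, category: Unhealthy_food, subcategory: Vending}
  - {tag: shop=alcohol,             layer: obesogenic, category: Unhealthy_food, subcategory: Alcohol}
  - {tag: amenity=bar,              layer: obesogenic, category: Unhealthy_food, subcategory: Alcohol}
  # --- protective: healthy food environment ---
  - {tag: shop=supermarket,         layer: protective, category: Healthy_food, subcategory: supermarket}
  - {tag: shop=greengrocer,         layer: protective, category: Healthy_food, subcategory: Greengrocer}
  - {tag: shop=farm,                layer: protective, category: Healthy_food, subcategory: Farm_shop}
  # --- protective: physical activity environment ---
  - {tag: leisure=fitness_centre,   layer: protective, category: Physical_activity, subcategory: gym}
  - {tag: leisure=sports_centre,    layer: protective, category: Physical_activity, subcategory: Sports_centre}
  - {tag: leisure=pitch,            layer: protective, category: Physical_activity, subcategory: Pitch}
  - {tag: leisure=swimming_pool,    layer: protective, category: Physical_activity, subcategory: Swimming}
  - {tag: sport=climbing,           layer: protective, category: Physical_activity, subcategory: Climbing}
  - {tag: sport=canoe,              layer: protective, category: Physical_activity, subcategory: Canoe}
  # --- protective: green space ---
  - {tag: leisure=park,             layer: protective, category: Green_space, subcategory: Park}
  - {tag: leisure=garden,           layer: protective, category: Green_space, subcategory: Garden}
  - {tag: landuse=forest,           layer: protective, category: Green_space, subcategory: Forest}
  # --- protective: public transport (walking access) ---
  - {tag: highway=bus_stop,         layer: protective, category: Public_transport, subcategory: Bus_stop}
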