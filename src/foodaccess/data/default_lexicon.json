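{
  "restaurant_categories": [
    "chinese", "japanese", "korean", "vietnamese", "thai", "filipino",
    "hawaiian", "asian fusion", "dim sum", "sushi bars", "ramen", "poke",
    "bubble tea", "indian", "pakistani", "laotian", "cambodian", "mongolian",
    "taiwanese", "indonesian", "malaysian", "burmese", "singaporean",
    "mexican", "traditional american", "new american", "italian", "french",
    "mediterranean", "greek", "pizza", "burgers", "sandwiches", "seafood",
    "steakhouses", "soul food", "barbeque", "breakfast & brunch", "diners",
    "fast food", "food trucks", "salad", "vegan", "vegetarian", "cafes",
    "ethiopian", "middle eastern", "spanish", "german", "caribbean",
    "latin american", "peruvian", "brazilian", "beer bar"
  ],
  "grocery_keywords": [
    "grocery", "farmer's market", "food market", "health market"
  ],
  "aapi_categories": [
    "chinese", "japanese", "korean", "vietnamese", "thai", "filipino",
    "hawaiian", "asian fusion", "dim sum", "sushi bars", "ramen", "poke",
    "bubble tea", "indian", "pakistani", "laotian", "cambodian", "mongolian",
    "taiwanese", "indonesian", "malaysian", "burmese", "singaporean",
    "asian grocery store", "japanese grocery", "korean grocery",
    "chinese grocery", "filipino grocery", "pan asian food market"
  ],
  "non_aapi_categories": [
    "mexican", "traditional american", "new american", "italian", "french",
    "mediterranean", "greek", "pizza", "burgers", "sandwiches",
    "steakhouses", "soul food", "barbeque", "breakfast & brunch", "diners",
    "fast food", "food trucks", "salad", "cafes", "ethiopian",
    "middle eastern", "spanish", "german", "caribbean", "latin american",
    "peruvian", "brazilian", "beer bar", "mexican grocery",
    "italian grocery", "european food market", "organic health market"
  ],
  "ambiguous_categories": [
    "grocery", "herbs & spices", "international grocery", "food market",
    "seafood markets", "farmer's market", "health market", "specialty food",
    "imported food", "tea rooms"
  ],
  "excluded_categories": [
    "bookstores", "food delivery services", "pop-up restaurants",
    "personal chefs", "street vendors", "pharmacy", "florists"
  ]
}
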