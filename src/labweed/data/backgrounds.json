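{
 "comment": "Lab reflection statistics of ten plant-free reference surfaces, transcribed as printed. Only mean and sigma are stored; the printed mean+/-sigma bound columns are derived (and inconsistent for 'Stone steps', which prints 14.05/14.05 against mean 13.55, sigma 0.50) and are recomputed on demand. 'aliases' records the alternate row labels used by the coverage table ('Flagged floor' = Stone steps, 'Concrete' = Fine chippings, 'Field' = Arable land).",
 "surfaces": [
  {"name": "Grey paving stones", "category": "anthropogenic", "aliases": ["Gray pavings"],
   "mean": {"L": 18.69, "a": 2.80, "b": 20.81}, "sigma": {"L": 0.62, "a": 1.00, "b": 0.54}},
  {"name": "Asphalt", "category": "anthropogenic", "aliases": ["Asphalt cover"],
   "mean": {"L": 12.91, "a": 2.16, "b": 13.53}, "sigma": {"L": 0.34, "a": 1.71, "b": 1.12}},
  {"name": "Gravel", "category": "anthropogenic",
   "mean": {"L": 7.44, "a": 3.15, "b": 12.24}, "sigma": {"L": 1.05, "a": 1.00, "b": 1.46}},
  {"name": "Stone steps", "category": "anthropogenic", "aliases": ["Flagged floor"],
   "mean": {"L": 13.55, "a": 2.34, "b": 15.44}, "sigma": {"L": 0.50, "a": 0.52, "b": 0.76}},
  {"name": "Fine chippings", "category": "anthropogenic", "aliases": ["Concrete"],
   "mean": {"L": 15.55, "a": 3.90, "b": 18.52}, "sigma": {"L": 0.55, "a": 0.50, "b": 0.84}},
  {"name": "Red paving stones", "category": "anthropogenic", "aliases": ["Red pavings"],
   "mean": {"L": 15.28, "a": 13.61, "b": 24.12}, "sigma": {"L": 1.28, "a": 2.89, "b": 0.91}},
  {"name": "Sandy path", "category": "anthropogenic",
   "mean": {"L": 11.45, "a": 4.90, "b": 19.72}, "sigma": {"L": 0.41, "a": 1.62, "b": 1.18}},
  {"name": "Arable land", "category": "natural", "aliases": ["Field"],
   "mean": {"L": 11.32, "a": 4.81, "b": 20.10}, "sigma": {"L": 0.13, "a": 0.70, "b": 0.47}},
  {"name": "Grassland", "category": "natural",
   "mean": {"L": 10.35, "a": -2.37, "b": 22.74}, "sigma": {"L": 0.96, "a": 2.40, "b": 2.06}},
  {"name": "Grassland with dew", "category": "natural", "aliases": ["Grassland+dew"],
   "mean": {"L": 9.80, "a": -6.32, "b": 19.47}, "sigma": {"L": 2.23, "a": 2.54, "b": 3.32}}
 ]
}
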