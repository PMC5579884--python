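{
 "comment": "Lab reflection statistics of four reference green color tones (bright to dark), transcribed verbatim. No standard deviation was measured; consumers fall back to the quarter-range convention sigma = |max - min| / 4 per channel. Several a-channel min/max pairs are printed in reversed order; Green 2's a-channel range (-16.83 ... -25.60) does not even bracket its mean (-26.18), and Green 3's L and b columns appear partially duplicated (both 32.95 ... 34.47). These cells are kept as printed and marked suspect rather than silently corrected.",
 "greens": [
  {"name": "Green 1",
   "median": {"L": 44.78, "a": -15.21, "b": 44.47},
   "mean":   {"L": 44.80, "a": -15.24, "b": 44.39},
   "min":    {"L": 44.71, "a": -14.85, "b": 43.79},
   "max":    {"L": 44.84, "a": -15.73, "b": 44.69},
   "flags": ["suspect-a"]},
  {"name": "Green 2",
   "median": {"L": 40.45, "a": -26.27, "b": 51.75},
   "mean":   {"L": 40.45, "a": -26.18, "b": 51.80},
   "min":    {"L": 40.39, "a": -16.83, "b": 50.82},
   "max":    {"L": 40.55, "a": -25.60, "b": 52.91},
   "flags": ["suspect-a"]},
  {"name": "Green 3",
   "median": {"L": 33.95, "a": -49.86, "b": 33.39},
   "mean":   {"L": 33.95, "a": -49.95, "b": 33.54},
   "min":    {"L": 32.95, "a": -49.61, "b": 32.95},
   "max":    {"L": 34.47, "a": -50.53, "b": 34.47},
   "flags": ["suspect-a", "suspect-L", "suspect-b"]},
  {"name": "Green 4",
   "median": {"L": 29.16, "a": -61.65, "b": -4.33},
   "mean":   {"L": 29.15, "a": -61.51, "b": -4.22},
   "min":    {"L": 28.98, "a": -63.01, "b": -3.25},
   "max":    {"L": 29.32, "a": -60.35, "b": -4.96},
   "flags": ["suspect-b"]}
 ]
}
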