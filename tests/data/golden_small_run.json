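{
 "description": "frozen summary of a seeded 4-participant synthetic run (seed 7, 2 trials/cell)",
 "accepted": 183,
 "placement_norm_3d_cm": 1.5716930460606457,
 "error_3d": [
  24.518155887874126,
  35.493667265487176,
  29.98981584654612,
  43.41857116190022,
  29.868919867851094,
  42.892604502202445,
  33.47112306185733,
  44.67896275713994
 ]
}
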