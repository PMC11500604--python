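{
  "_comment": "Reconstructed structure-wise ERP placeholders (ms) for the non-personalized heterogeneous scenario B; spans 140-180 ms with an area-typical mean near 159 ms. Edit freely.",
  "anterior": 158,
  "posterior": 165,
  "lateral": 162,
  "septal": 150,
  "inferior": 155,
  "appendage": 172,
  "veins": 140,
  "default": 157
}
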