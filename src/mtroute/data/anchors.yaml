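# Default route-model anchors: published clade ages pinned at the route ends.
west:
  name: L3
  place: Khor Angar (Djibouti)
  coordinates: 12°23´N-43°21´E
  age_ky: 70.8
  ci95_ky: [52.7, 88.1]
east:
  name: S
  place: Darwin (Australia)
  coordinates: 12°28´S-130°50´E
  age_ky: 46.8
  ci95_ky: [37.0, 56.9]
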