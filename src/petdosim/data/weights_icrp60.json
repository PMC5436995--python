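{
 "name": "ICRP60",
 "weights": {
  "gonads": 0.20,
  "red_marrow": 0.12,
  "colon": 0.12,
  "lungs": 0.12,
  "stomach_wall": 0.12,
  "urinary_bladder_wall": 0.05,
  "breasts": 0.05,
  "liver": 0.05,
  "esophagus": 0.05,
  "thyroid": 0.05,
  "skin": 0.01,
  "osteogenic_cells": 0.01,
  "remainder": 0.05
 },
 "remainder_tissues": [
  "adrenals",
  "brain",
  "small_intestine",
  "kidneys",
  "muscle",
  "pancreas",
  "spleen",
  "thymus",
  "uterus"
 ],
 "remainder_rule": "mass_weighted",
 "surrogate_map": {
  "esophagus": "thymus"
 }
}
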