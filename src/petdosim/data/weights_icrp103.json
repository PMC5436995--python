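{
 "name": "ICRP103",
 "weights": {
  "red_marrow": 0.12,
  "colon": 0.12,
  "lungs": 0.12,
  "stomach_wall": 0.12,
  "breasts": 0.12,
  "remainder": 0.12,
  "gonads": 0.08,
  "urinary_bladder_wall": 0.04,
  "esophagus": 0.04,
  "liver": 0.04,
  "thyroid": 0.04,
  "osteogenic_cells": 0.01,
  "brain": 0.01,
  "salivary_glands": 0.01,
  "skin": 0.01
 },
 "remainder_tissues": [
  "adrenals",
  "gallbladder_wall",
  "heart_wall",
  "kidneys",
  "muscle",
  "oral_mucosa",
  "pancreas",
  "small_intestine",
  "spleen",
  "thymus",
  "uterus"
 ],
 "remainder_rule": "arithmetic_mean",
 "surrogate_map": {
  "esophagus": "thymus",
  "salivary_glands": "brain",
  "oral_mucosa": "brain"
 }
}
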