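{
 "comment": "SYNTHETIC cylindrical dimension sets for the choroid plexuses of the lateral ventricles (body, atrial and temporal parts, bilateral). The underlying MR morphometry is not redistributable; these dimensions are calibrated so that the unit-density cylinder masses reproduce the published estimates of 2.76 g (male) and 1.81 g (female).",
 "density_g_per_cm3": 1.0,
 "bilateral": true,
 "male": [
  {"label": "body", "length_mm": 40.0, "width_mm": 3.3122},
  {"label": "atrial", "length_mm": 25.0, "width_mm": 5.1891},
  {"label": "temporal", "length_mm": 30.0, "width_mm": 4.6371}
 ],
 "female": [
  {"label": "body", "length_mm": 36.0, "width_mm": 2.8395},
  {"label": "atrial", "length_mm": 22.0, "width_mm": 4.4485},
  {"label": "temporal", "length_mm": 27.0, "width_mm": 3.9752}
 ]
}
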