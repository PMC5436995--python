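{
 "name": "Ga-68",
 "half_life_h": 1.1285,
 "lambda_phys_per_h": 0.6142199207443024,
 "delta_np_mev": 0.7387,
 "photon_lines": [
  [1.7782, 0.511],
  [0.0322, 1.07734]
 ],
 "beta_plus_branches": [
  [0.8772, 1.8992],
  [0.0119, 0.8219]
 ],
 "provenance": "frozen from a published decay-data compilation: T1/2 = 67.71 min; beta+ branches 87.72% (E_max 1.8992 MeV) and 1.19% (E_max 0.8219 MeV); annihilation photon yield 2 x 0.8891; principal gamma 1077.34 keV at 3.22%; delta_np is the mean beta+ energy per decay plus Auger/conversion electrons"
}
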