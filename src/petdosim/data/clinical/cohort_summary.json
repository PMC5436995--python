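{
 "comment": "Published summary values from the five-patient male Ga-68-NODAGA-RGDyK dosimetry cohort (doses mGy/MBq, EDs mSv/MBq, residence times hours). Used as desk-scale inputs and calibration anchors; the per-patient raw data were never deposited.",
 "injected_activity_mbq": 200.0,
 "n_patients": 5,
 "voiding_interval_measured_h": 0.5,
 "ed_msv_per_mbq": {
  "icrp60_male_30min": 1.57e-02,
  "icrp60_male_30min_sd": 1.50e-03,
  "icrp60_male_1h": 1.93e-02,
  "icrp60_male_1h_sd": 1.95e-03,
  "icrp103_male_30min": 1.65e-02,
  "icrp103_male_30min_sd": 1.68e-03,
  "icrp103_male_1h": 1.98e-02,
  "icrp103_male_1h_sd": 1.98e-03,
  "icrp60_female_1h": 2.43e-02,
  "icrp103_female_1h": 2.25e-02,
  "icrp60_reference_1h": 2.07e-02,
  "icrp103_reference_1h": 1.90e-02
 },
 "choroid_plexuses": {
  "residence_time_h": 3.08e-04,
  "residence_time_min_h": 1.35e-04,
  "residence_time_max_h": 3.66e-04,
  "residence_time_sd_h": 9.88e-05,
  "mass_male_g": 2.76,
  "mass_female_g": 1.81,
  "dose_male_mgy_per_mbq": 3.96e-02,
  "dose_female_mgy_per_mbq": 5.66e-02
 },
 "phantom_scan": {
  "activity_mbq": 42.3,
  "volume_ml": 9340.0,
  "expected_kbq_per_ml": 4.52,
  "measured_kbq_per_ml": 4.25,
  "recovery_bias_percent": -6
 },
 "bladder_voiding_tau_increase_percent": 74,
 "ed_increment_percent_male": 23,
 "ed_increment_percent_female": 24
}
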