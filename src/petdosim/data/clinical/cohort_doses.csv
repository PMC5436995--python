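organ,residence_time_h,residence_time_sd_h,dose_male_30min,dose_male_30min_sd,dose_male_1h,dose_male_1h_sd,dose_female_1h,dose_reference_1h
adrenals,,,6.40E-03,5.42E-04,6.42E-03,5.37E-04,8.18E-03,7.30E-03
brain,3.20E-03,7.09E-04,1.77E-03,2.64E-04,1.77E-03,2.64E-04,2.15E-03,1.96E-03
breasts,,,4.58E-03,2.99E-04,4.58E-03,2.96E-04,5.86E-03,5.22E-03
gallbladder_wall,,,7.01E-03,6.41E-04,7.07E-03,6.44E-04,8.69E-03,7.88E-03
lli_wall,8.87E-03,2.38E-03,2.05E-02,4.03E-03,2.12E-02,4.04E-03,2.41E-02,2.27E-02
small_intestine,4.52E-02,1.14E-02,3.01E-02,6.43E-03,3.03E-02,6.45E-03,3.54E-02,3.29E-02
stomach_wall,6.16E-03,2.06E-03,1.13E-02,1.95E-03,1.13E-02,1.97E-03,1.36E-02,1.25E-02
uli_wall,1.16E-02,3.35E-03,1.85E-02,3.78E-03,1.87E-02,3.77E-03,2.18E-02,2.03E-02
heart_wall,1.41E-02,3.12E-03,1.29E-02,1.83E-03,1.29E-02,1.83E-03,1.53E-02,1.41E-02
kidneys,2.86E-02,7.27E-03,4.63E-02,1.14E-02,4.64E-02,1.13E-02,5.06E-02,4.85E-02
liver,5.11E-02,1.31E-02,1.55E-02,3.64E-03,1.56E-02,3.61E-03,2.08E-02,1.82E-02
lungs,3.01E-02,3.92E-03,1.55E-02,1.90E-03,1.55E-02,1.90E-03,1.93E-02,1.74E-02
muscle,,,5.28E-03,3.72E-04,5.45E-03,3.87E-04,6.88E-03,6.17E-03
ovaries,,,,,,,1.04E-02,9.28E-03
pancreas,1.43E-03,7.16E-04,1.01E-02,3.70E-03,1.01E-02,3.68E-03,1.16E-02,1.09E-02
red_marrow,1.44E-02,2.81E-03,7.12E-03,3.84E-04,7.23E-03,3.79E-04,7.98E-03,7.61E-03
osteogenic_cells,,,8.57E-03,4.09E-04,8.64E-03,4.10E-04,1.17E-02,1.02E-02
skin,,,4.36E-03,2.95E-04,4.43E-03,2.98E-04,5.60E-03,5.02E-03
spleen,1.08E-02,7.26E-03,2.98E-02,1.85E-02,2.98E-02,1.85E-02,3.60E-02,3.28E-02
testes,,,5.34E-03,3.77E-04,5.81E-03,4.43E-04,,2.91E-03
thymus,,,5.24E-03,3.33E-04,5.24E-03,3.33E-04,6.68E-03,5.96E-03
thyroid,3.99E-04,2.10E-04,9.81E-03,4.29E-03,9.81E-03,4.29E-03,1.17E-02,1.08E-02
urinary_bladder_wall,7.32E-02,1.51E-02,8.94E-02,1.73E-02,1.51E-01,2.99E-02,2.03E-01,1.77E-01
uterus,,,,,,,1.20E-02,1.09E-02
total_body,8.77E-01,6.75E-02,6.49E-03,5.24E-04,6.68E-03,5.32E-04,8.46E-03,7.57E-03
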