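organ,mass_g
adrenals,14.0
brain,1200.0
breasts,360.0
gallbladder_wall,8.0
lli_wall,140.0
small_intestine,600.0
stomach_wall,140.0
uli_wall,200.0
heart_wall,240.0
kidneys,275.0
liver,1400.0
lungs,800.0
muscle,17000.0
ovaries,8.71
pancreas,85.0
red_marrow,1050.0
osteogenic_cells,104.0
skin,2118.0
spleen,150.0
thymus,28.4
thyroid,17.0
urinary_bladder_wall,35.9
urinary_bladder_contents,160.0
uterus,79.0
total_body,56800.0
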