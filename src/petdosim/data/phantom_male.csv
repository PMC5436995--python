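organ,mass_g
adrenals,16.3
brain,1420.0
breasts,351.0
gallbladder_wall,10.5
lli_wall,160.0
small_intestine,677.0
stomach_wall,158.0
uli_wall,220.0
heart_wall,316.0
kidneys,299.0
liver,1910.0
lungs,1000.0
muscle,28000.0
pancreas,94.3
red_marrow,1120.0
osteogenic_cells,120.0
skin,3010.0
spleen,183.0
testes,39.1
thymus,20.9
thyroid,20.7
urinary_bladder_wall,47.6
urinary_bladder_contents,211.0
total_body,73700.0
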