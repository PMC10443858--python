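species,parameter,in_vivo_mean,in_vivo_sd,measured_mean,measured_sd,unit,n,source
mouse,corneal_diameter,2.70,0.24,2.42,0.11,mm,5,own measurement
rat,corneal_diameter,5.50,0.0,4.80,0.28,mm,4,own measurement
rabbit,corneal_diameter,13.63,0.41,11.79,0.68,mm,3,own measurement
mouse,ocular_axial_length,3.00,0.04,2.77,0.18,mm,5,literature
rat,ocular_axial_length,6.29,0.26,5.13,0.30,mm,4,literature
rabbit,ocular_axial_length,17.10,0.41,14.68,0.36,mm,3,literature
mouse,central_retinal_thickness,186.90,15.10,172.95,28.0,um,5,literature
rat,central_retinal_thickness,199.2,7,144.82,24.40,um,4,literature
rabbit,central_retinal_thickness,194.30,7.70,160.39,33.34,um,3,literature
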