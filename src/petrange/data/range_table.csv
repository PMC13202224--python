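isotope,half_life_min,e_beta_max_mev,material,density_g_cm3,r_median_mm,provenance
F-18,110,0.63,EPF,0.20,2.12,published
F-18,110,0.63,PLA,1.30,0.34,published
F-18,110,0.63,Rigid10k,1.70,0.24,published
Zr-89,4704,0.90,EPF,0.20,4.31,published
Zr-89,4704,0.90,PLA,1.30,0.70,published
Zr-89,4704,0.90,Rigid10k,1.70,0.49,published
Ga-68,68,1.90,EPF,0.20,12.02,published
Ga-68,68,1.90,PLA,1.30,1.97,published
Ga-68,68,1.90,Rigid10k,1.70,1.37,published
F-18,110,0.63,water,1.00,0.424,derived-from-low-density-cell
Zr-89,4704,0.90,water,1.00,0.862,derived-from-low-density-cell
Ga-68,68,1.90,water,1.00,2.404,derived-from-low-density-cell
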