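isotope,field_t,orientation,vpr_1.5,vpr_1.2,vpr_1.0,vpr_0.9,vpr_0.8,vpr_0.7
F-18,0,parallel,0.200,0.469,0.609,0.668,0.927,0.941
F-18,9.4,parallel,0.161,0.379,0.388,0.619,0.922,0.942
Zr-89,0,parallel,0.385,0.670,0.782,0.815,0.968,0.977
Zr-89,9.4,parallel,0.188,0.395,0.518,0.644,0.922,0.950
Ga-68,0,parallel,0.739,0.970,0.976,0.941,0.975,0.978
Ga-68,9.4,parallel,0.290,0.566,0.752,0.803,0.962,0.975
Ga-68,9.4,perpendicular,0.659,0.729,0.886,0.945,0.937,0.973
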