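site,layer,density_mean,density_se,c_biomass_mean,c_biomass_se,n_biomass_mean,n_biomass_se,n_cores
NOW,0-5 cm,10538,860,2465,203,422,38,15
NOW,5-10 cm,414,46,725,306,145,72,15
LS,0-5 cm,7949,488,1937,340,441,81,15
LS,5-10 cm,407,99,173,31,39,7,15
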