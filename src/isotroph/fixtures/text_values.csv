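name,site,taxon,value,unit,provenance
taxon_d15n,NOW,Ampharetidae,9.2,permil,results_text
taxon_d15n,LS,Ampharetidae,12.5,permil,results_text
taxon_d15n,NOW,Opheliidae,14.4,permil,results_text
taxon_d15n,LS,Opheliidae,16.7,permil,results_text
taxon_d15n,NOW,Bivalvia,7.7,permil,results_text
taxon_d15n,LS,Bivalvia,12.3,permil,results_text
taxon_tl,NOW,Ampharetidae,1.5,TL,results_text
taxon_tl,LS,Ampharetidae,2.1,TL,results_text
taxon_tl,NOW,Opheliidae,2.8,TL,results_text
taxon_tl,LS,Opheliidae,3.2,TL,results_text
taxon_tl,NOW,Bivalvia,1.1,TL,results_text
taxon_tl,LS,Bivalvia,2.1,TL,results_text
taxon_tl,LS,Nereis sp.,1.6,TL,results_text
taxon_tl,LS,Lumbrineridae,1.8,TL,results_text
taxon_tl,NOW,Lumbrineridae,2.1,TL,results_text
taxon_tl,LS,Diastylidae,0.6,TL,results_text
d15n_range_min,NOW,,7.3,permil,results_text
d15n_range_max,NOW,,14.4,permil,results_text
d15n_range_min,LS,,7.0,permil,results_text
d15n_range_max,LS,,16.7,permil,results_text
tl_range_min,NOW,,1.0,TL,results_text
tl_range_max,NOW,,2.8,TL,results_text
tl_range_min,LS,,0.7,TL,results_text
tl_range_max,LS,,3.2,TL,results_text
mean_tl,NOW,,2.0,TL,results_text
mean_tl_sd,NOW,,0.7,TL,results_text
mean_tl,LS,,2.1,TL,results_text
mean_tl_sd,LS,,0.6,TL,results_text
layman_cd,NOW,,2.64,permil,results_text
layman_cd,LS,,1.98,permil,results_text
layman_nnd,NOW,,2.78,permil,results_text
layman_nnd,LS,,2.45,permil,results_text
density_total,NOW,,10952,ind m-2,abstract
density_total,LS,,8355,ind m-2,abstract
c_biomass_total,NOW,,3190,mg C m-2,abstract
c_biomass_total,LS,,2110,mg C m-2,abstract
megafauna_c_biomass,LS,,3666,mg C m-2,results_text
megafauna_n_biomass,LS,,833,mg N m-2,results_text
diet_pom_min,NOW,SDF,0.591,proportion,results_text
diet_pom_max,LS,SSDF,0.795,proportion,results_text
d13c_mean,NOW,,-23.4,permil,results_text
d13c_sd,NOW,,1.0,permil,results_text
d13c_mean,LS,,-23.7,permil,results_text
d13c_sd,LS,,1.2,permil,results_text
tl_class_count_1,NOW,,6,taxa,results_text
tl_class_count_2,NOW,,8,taxa,results_text
tl_class_count_1,LS,,4,taxa,results_text
tl_class_count_2,LS,,12,taxa,results_text
tl_class_count_3,LS,,1,taxa,results_text
baseline_d15n,NOW,,7.4,permil,table1
baseline_d15n,LS,,8.3,permil,table1
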