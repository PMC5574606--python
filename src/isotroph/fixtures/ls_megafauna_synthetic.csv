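core_id,site,layer,taxon,guild,count,c_biomass_mg,n_biomass_mg,area_m2,fragment_flag
LS-01,LS,0-5 cm,Bathyarca glacialis,FF,1,4.798794,1.090397,0.003927,False
LS-02,LS,0-5 cm,Bathyarca glacialis,FF,1,4.798794,1.090397,0.003927,False
LS-07,LS,0-5 cm,Bathyarca glacialis,FF,1,4.798794,1.090397,0.003927,False
LS-01,LS,0-5 cm,Prionospio cirrifera,FF/SDF,6,1.62,0.25,0.003927,False
LS-01,LS,0-5 cm,Thyasiridae,FF/SDF,9,2.07,0.31,0.003927,False
LS-01,LS,5-10 cm,Maldane sarsi,SSDF,1,0.41,0.06,0.003927,False
LS-02,LS,0-5 cm,Prionospio sp.,FF/SDF,4,0.96,0.15,0.003927,False
LS-02,LS,0-5 cm,unidentified juvenile bivalves,unknown,7,0.84,0.13,0.003927,False
LS-02,LS,5-10 cm,Asychis spp.,SSDF,1,0.44,0.07,0.003927,False
LS-07,LS,0-5 cm,Ampharetidae,SDF,2,0.82,0.12,0.003927,False
LS-07,LS,0-5 cm,Leptostylis spp.,FF/SDF,3,0.45,0.07,0.003927,False
LS-07,LS,0-5 cm,unidentified polychaete fragments,unknown,0,0.58,0.09,0.003927,True
LS-07,LS,5-10 cm,Nephtyidae,P/S,1,0.39,0.06,0.003927,False
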