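taxon,site,guild,layer,d13c,d15n,n_pooled,preserved_formalin,d15n_provenance
Ampharetidae,NOW,SDF,pooled,-23.4,9.2,4,False,printed
Opheliidae,NOW,SSDF,pooled,-22.0,14.4,3,False,printed
Bivalvia,NOW,FF/SDF,pooled,-24.8,7.7,6,False,printed
Lumbrineridae,NOW,P/S,pooled,-22.9,11.6,3,False,back-computed
Eudorellopsis integra,NOW,FF/SDF,pooled,-23.8,7.3,12,False,back-computed
Diastylidae,NOW,FF/SDF,pooled,-24.1,7.9,5,False,synthetic
Cossura spp.,NOW,SSDF,pooled,-23.0,10.9,7,False,synthetic
Chaetozone spp.,NOW,FF/SDF,pooled,-23.5,10.2,6,False,synthetic
Prionospio cirrifera,NOW,FF/SDF,pooled,-25.3,9.8,9,False,synthetic
Nephtyidae,NOW,P/S,pooled,-21.3,12.8,2,False,synthetic
Cirratulidae,NOW,FF/SDF,pooled,-23.9,10.5,5,False,synthetic
Maldanidae,NOW,SSDF,pooled,-22.6,12.2,2,False,synthetic
Euchone spp.,NOW,FF,pooled,-24.4,9.4,4,False,synthetic
Terebellidae,NOW,SDF,pooled,-23.2,11.0,3,False,synthetic
Ampharetidae,LS,SDF,pooled,-23.7,12.5,3,False,printed
Opheliidae,LS,SSDF,pooled,-22.1,16.7,2,False,printed
Bivalvia,LS,FF/SDF,pooled,-25.0,12.3,8,False,printed
Nereis sp.,LS,P/S,pooled,-23.2,10.6,2,False,back-computed
Lumbrineridae,LS,P/S,pooled,-22.6,11.3,3,False,back-computed
Diastylidae,LS,FF/SDF,pooled,-24.6,6.96,6,False,back-computed
Leptostylis spp.,LS,FF/SDF,pooled,-25.1,8.0,5,False,synthetic
Thyasiridae,LS,FF/SDF,pooled,-26.3,12.0,10,False,synthetic
Prionospio cirrifera,LS,FF/SDF,pooled,-24.9,11.5,8,False,synthetic
Spionidae,LS,FF/SDF,pooled,-25.4,11.8,6,False,synthetic
Nephtyidae,LS,P/S,pooled,-22.4,13.5,2,False,synthetic
Aglaophamus sp.,LS,P/S,pooled,-21.5,14.0,2,False,synthetic
Sphaerodoridae,LS,SSDF,pooled,-22.9,14.8,3,False,synthetic
Maldane sarsi,LS,SSDF,pooled,-23.3,12.6,3,False,synthetic
Asychis spp.,LS,SSDF,pooled,-23.6,12.1,4,False,synthetic
Golfingiidae,LS,SDF,pooled,-24.2,10.9,4,False,synthetic
Capitellidae,LS,unknown,pooled,-23.9,10.4,5,False,synthetic
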