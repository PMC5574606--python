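taxon,rank,now_density_pct,now_c_pct,now_n_pct,ls_density_pct,ls_c_pct,ls_n_pct,guild
Nemertea,phylum,<1,4.0,4.0,<1,<1,<1,
Platyhelminthes,phylum,,,,<1,<1,<1,
Porifera,phylum,,,,<1,<1,<1,FF
Sipuncula,phylum,<1,<1,<1,5.1,1.0,1.1,
Golfingiidae,family,,,,<1,<1,<1,SDF
Ascidiacea,class,<1,<1,<1,,,,FF
Actiniaria,order,<1,2.2,2.2,,,,P/S
Echinodermata total,group,1.1,1.6,2.0,1.3,<1,<1,
Ophiurida,order,<1,<1,<1,<1,<1,<1,FF/SDF
Amphiuridae,family,<1,<1,<1,,,,FF/SDF
Ophiolepididae,family,<1,<1,<1,,,,FF/SDF
Chaetoderma sp.,genus,,,,<1,<1,<1,P/S
Bivalvia total,group,4.8,9.6,10.1,40.8,7.9,7.2,
unidentified juvenile bivalves,group,3.7,5.9,6.2,19.8,3.0,2.7,
Arcidae,family,,,,<1,<1,<1,FF
Mytilidae,family,<1,<1,<1,,,,FF
Cuspidaria sp.,genus,,,,<1,<1,<1,P/S
Nucula sp.,genus,<1,<1,<1,,,,FF/SDF
Pectinidae,family,,,,<1,1.5,1.4,FF
Thyasiridae,family,<1,<1,<1,20.2,3.2,2.8,FF/SDF
Thyasira sp.,genus,<1,2.7,2.9,,,,FF/SDF
Yoldiidae,family,,,,<1,<1,<1,FF/SDF
Crustacea total,group,57.3,10.5,7.4,7.6,3.8,2.6,
Ampeliscidae,family,<1,<1,<1,,,,FF
Lysianassidae,family,<1,<1,<1,,,,P/S
Arrhis sp.,genus,<1,<1,<1,<1,<1,<1,FF/SDF
Monoculodes sp.,genus,<1,<1,<1,,,,P/S
Diastylidae,family,1.3,<1,<1,<1,<1,<1,FF/SDF
Diastylis spp.,genus,1.4,<1,<1,<1,1.0,<1,FF/SDF
Leptostylis spp.,genus,,,,1.7,<1,<1,FF/SDF
Leuconidae,family,<1,<1,<1,<1,<1,<1,FF/SDF
Eudorella sp.,genus,<1,<1,<1,<1,<1,<1,FF/SDF
Eudorellopsis integra,species,45.4,7.2,4.9,,,,FF/SDF
Eudorellopsis spp.,genus,1.9,<1,<1,,,,FF/SDF
Leucon spp.,genus,<1,<1,<1,1.1,<1,<1,FF/SDF
Desmosomatidae,family,1.6,<1,<1,<1,<1,<1,
Desmosoma sp.,genus,<1,<1,<1,,,,SSDF
Eugerda sp.,genus,<1,<1,<1,,,,SSDF
Leptognathia sp.,genus,<1,<1,<1,,,,FF/SDF
Pseudosphyrapus sp.,genus,1.8,<1,<1,,,,P/S
Polychaeta total,group,35.3,71.9,74.0,42.7,86.4,88.2,
unidentified polychaete fragments,group,,14.8,13.8,,12.9,13.0,
Ampharetidae,family,,,,1.1,6.5,5.7,SDF
Ampharete sp.,genus,<1,<1,<1,<1,<1,<1,SDF
Capitellidae,family,<1,<1,<1,<1,<1,<1,
Cirratulidae,family,2.4,3.9,3.8,,,,
Chaetozone spp.,genus,3.7,9.0,8.0,<1,<1,<1,FF/SDF
Cossura pygodactylata,species,<1,<1,<1,,,,SSDF
Cossura spp.,genus,8.7,2.6,1.0,<1,<1,<1,SSDF
Lumbrineridae,family,0.0,1.3,1.4,<1,1.4,1.5,P/S
Scoletoma spp.,genus,<1,1.1,1.1,<1,<1,<1,P/S
Maldanidae,family,0.0,16.2,21.1,3.4,6.5,6.4,
Asychis spp.,genus,,,,2.3,5.3,5.1,SSDF
Maldane sarsi,species,,,,1.1,1.0,<1,SSDF
Maldane spp.,genus,,,,1.5,1.2,1.2,SSDF
Nephtyidae,family,<1,<1,<1,<1,<1,<1,P/S
Aglaophamus malmgreni,species,,,,1.1,10.3,11.1,P/S
Aglaophamus sp.,genus,,,,<1,15.3,16.6,P/S
Nereis sp.,genus,,,,<1,<1,<1,P/S
Opheliidae,family,,,,<1,<1,<1,
Ophelina cylindricaudata,species,<1,<1,<1,,,,SSDF
Scoloplos group armiger,species,<1,<1,<1,<1,<1,<1,SSDF
Aricidea spp.,genus,<1,<1,<1,,,,SDF
Euchone spp.,genus,<1,<1,<1,,,,FF
Sphaerodoridium minutum,species,,,,<1,<1,<1,SSDF
Spionidae,family,<1,1.6,1.7,1.3,7.3,7.5,
Prionospio cirrifera,species,7.9,8.8,8.8,12.6,9.4,9.6,FF/SDF
Prionospio sp.,genus,4.2,5.2,5.3,8.2,3.8,3.9,FF/SDF
Anguillosyllis spp.,genus,,,,<1,<1,<1,SDF
Syllides sp.,genus,<1,<1,<1,,,,P/S
Terebellidae,family,,3.9,4.6,<1,<1,<1,
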