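taxon_id,name,higher_group,eutrophic,oligotrophic,mesosaprobiont,endemic,saprobic_valence,valence_source
anabaena_lemmermannii,Anabaena lemmermannii,Cyanophyta,1,0,0,0,2.0,placeholder_non_authoritative
asterionella_formosa,Asterionella formosa,Bacillariophyta,1,0,1,0,2.0,placeholder_non_authoritative
ceratium_hirundinella,Ceratium hirundinella,Miozoa,0,0,0,0,2.0,placeholder_non_authoritative
dinobryon_cylindricum,Dinobryon cylindricum,Ochrophyta,0,0,1,0,2.0,placeholder_non_authoritative
dinobryon_divergens,Dinobryon divergens,Ochrophyta,0,0,1,0,2.0,placeholder_non_authoritative
dinobryon_sociale,Dinobryon sociale,Ochrophyta,0,0,1,0,2.0,placeholder_non_authoritative
gymnodinium_coeruleum,Gymnodinium coeruleum,Miozoa,0,0,0,0,2.0,placeholder_non_authoritative
rhodomonas_pusilla,Rhodomonas pusilla,Cryptophyta,0,1,1,0,2.0,placeholder_non_authoritative
spirogyra_sp_plankton,Spirogyra sp. (plankton),Charophyta,1,0,0,0,2.0,placeholder_non_authoritative
fragilaria_radians,Fragilaria radians,Bacillariophyta,0,0,0,0,2.0,placeholder_non_authoritative
picoplankton,picoplankton,Picoplankton,0,0,0,0,,
asplanchna_priodonta,Asplanchna priodonta,Rotifera,1,0,0,0,2.0,placeholder_non_authoritative
bosmina_longirostris,Bosmina longirostris,Cladocera,1,0,0,0,2.0,placeholder_non_authoritative
cyclops_kolensis,Cyclops kolensis,Copepoda,0,1,0,0,2.0,placeholder_non_authoritative
daphnia_galeata,Daphnia galeata,Cladocera,0,0,0,0,2.0,placeholder_non_authoritative
epischura_baikalensis,Epischura baikalensis,Copepoda,0,1,0,1,2.0,placeholder_non_authoritative
leptodora_kindtii,Leptodora kindtii,Cladocera,0,0,0,0,2.0,placeholder_non_authoritative
synchaeta_grandis,Synchaeta grandis,Rotifera,0,0,0,0,2.0,placeholder_non_authoritative
spirogyra_sp_benthos,Spirogyra sp. (benthos),Charophyta,1,0,1,0,2.0,placeholder_non_authoritative
chaetocladiella_pumila,Chaetocladiella pumila,Chlorophyta,0,1,0,1,2.0,placeholder_non_authoritative
cladophora_floccosa,Cladophora floccosa,Chlorophyta,0,0,0,1,2.0,placeholder_non_authoritative
draparnaldioides_baicalensis,Draparnaldioides baicalensis,Chlorophyta,0,1,0,1,2.0,placeholder_non_authoritative
draparnaldioides_pilosa,Draparnaldioides pilosa,Chlorophyta,0,1,0,1,2.0,placeholder_non_authoritative
tetraspora_cylindrica_bullosa,Tetraspora cylindrica var. bullosa,Chlorophyta,0,0,0,1,2.0,placeholder_non_authoritative
schizothrix_sp,Schizothrix sp.,Cyanophyta,0,0,0,0,2.0,placeholder_non_authoritative
cocconeis_placentula,Cocconeis placentula,Bacillariophyta,0,0,1,0,2.0,placeholder_non_authoritative
cymatopleura_solea,Cymatopleura solea,Bacillariophyta,0,0,1,0,2.0,placeholder_non_authoritative
didymosphenia_grunowii,Didymosphenia grunowii,Bacillariophyta,0,0,0,1,2.0,placeholder_non_authoritative
encyonema_pseudoturgidum,Encyonema pseudoturgidum,Bacillariophyta,0,0,0,1,2.0,placeholder_non_authoritative
hannaea_baicalensis,Hannaea baicalensis,Bacillariophyta,0,1,0,1,2.0,placeholder_non_authoritative
nitzschia_dissipata,Nitzschia dissipata,Bacillariophyta,0,0,1,0,2.0,placeholder_non_authoritative
nitzschia_recta,Nitzschia recta,Bacillariophyta,0,0,1,0,2.0,placeholder_non_authoritative
yasnitskya_tatyanae,Yasnitskya tatyanae,Bacillariophyta,0,0,0,1,2.0,placeholder_non_authoritative
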