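community,higher_group,n_taxa
plankton,Chlorophyta,18
plankton,Bacillariophyta,16
plankton,Cyanophyta,8
plankton,Ochrophyta,7
plankton,Miozoa,4
plankton,Cryptophyta,2
plankton,Charophyta,1
plankton,Rotifera,20
plankton,Cladocera,10
plankton,Copepoda,6
benthic_macroalgae,Chlorophyta,17
benthic_macroalgae,Cyanophyta,8
benthic_macroalgae,Charophyta,4
benthic_macroalgae,Ochrophyta,1
benthic_microalgae,Bacillariophyta,52
benthic_macrophytes,Macrophyta,6
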