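# Approximate assignment of the 68 Desikan-Killiany cortical regions to
# five coarse functional areas (executive, pre/motor, parietal, temporal,
# occipital). Editable; the grouping is a pragmatic default, not an
# anatomical ground truth.
region,hemisphere,area
lh_bankssts,lh,temporal
lh_caudalanteriorcingulate,lh,executive
lh_caudalmiddlefrontal,lh,pre/motor
lh_cuneus,lh,occipital
lh_entorhinal,lh,temporal
lh_frontalpole,lh,executive
lh_fusiform,lh,temporal
lh_inferiorparietal,lh,parietal
lh_inferiortemporal,lh,temporal
lh_insula,lh,executive
lh_isthmuscingulate,lh,parietal
lh_lateraloccipital,lh,occipital
lh_lateralorbitofrontal,lh,executive
lh_lingual,lh,occipital
lh_medialorbitofrontal,lh,executive
lh_middletemporal,lh,temporal
lh_paracentral,lh,pre/motor
lh_parahippocampal,lh,temporal
lh_parsopercularis,lh,pre/motor
lh_parsorbitalis,lh,executive
lh_parstriangularis,lh,executive
lh_pericalcarine,lh,occipital
lh_postcentral,lh,parietal
lh_posteriorcingulate,lh,parietal
lh_precentral,lh,pre/motor
lh_precuneus,lh,parietal
lh_rostralanteriorcingulate,lh,executive
lh_rostralmiddlefrontal,lh,executive
lh_superiorfrontal,lh,pre/motor
lh_superiorparietal,lh,parietal
lh_superiortemporal,lh,temporal
lh_supramarginal,lh,parietal
lh_temporalpole,lh,temporal
lh_transversetemporal,lh,temporal
rh_bankssts,rh,temporal
rh_caudalanteriorcingulate,rh,executive
rh_caudalmiddlefrontal,rh,pre/motor
rh_cuneus,rh,occipital
rh_entorhinal,rh,temporal
rh_frontalpole,rh,executive
rh_fusiform,rh,temporal
rh_inferiorparietal,rh,parietal
rh_inferiortemporal,rh,temporal
rh_insula,rh,executive
rh_isthmuscingulate,rh,parietal
rh_lateraloccipital,rh,occipital
rh_lateralorbitofrontal,rh,executive
rh_lingual,rh,occipital
rh_medialorbitofrontal,rh,executive
rh_middletemporal,rh,temporal
rh_paracentral,rh,pre/motor
rh_parahippocampal,rh,temporal
rh_parsopercularis,rh,pre/motor
rh_parsorbitalis,rh,executive
rh_parstriangularis,rh,executive
rh_pericalcarine,rh,occipital
rh_postcentral,rh,parietal
rh_posteriorcingulate,rh,parietal
rh_precentral,rh,pre/motor
rh_precuneus,rh,parietal
rh_rostralanteriorcingulate,rh,executive
rh_rostralmiddlefrontal,rh,executive
rh_superiorfrontal,rh,pre/motor
rh_superiorparietal,rh,parietal
rh_superiortemporal,rh,temporal
rh_supramarginal,rh,parietal
rh_temporalpole,rh,temporal
rh_transversetemporal,rh,temporal
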