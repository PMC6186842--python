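{
 "Precentral_L": "SMA",
 "Precentral_R": "SMA",
 "Postcentral_L": "SMA",
 "Postcentral_R": "SMA",
 "Supp_Motor_Area_L": "SMA",
 "Supp_Motor_Area_R": "SMA",
 "Paracentral_Lobule_L": "SMA",
 "Paracentral_Lobule_R": "SMA",
 "Rolandic_Oper_L": "SMA",
 "Rolandic_Oper_R": "SMA",
 "Frontal_Sup_L": "ATT",
 "Frontal_Sup_R": "ATT",
 "Frontal_Mid_L": "ATT",
 "Frontal_Mid_R": "ATT",
 "Frontal_Inf_Oper_L": "ATT",
 "Frontal_Inf_Oper_R": "ATT",
 "Frontal_Inf_Tri_L": "ATT",
 "Frontal_Inf_Tri_R": "ATT",
 "Parietal_Sup_L": "ATT",
 "Parietal_Sup_R": "ATT",
 "Parietal_Inf_L": "ATT",
 "Parietal_Inf_R": "ATT",
 "Supramarginal_L": "ATT",
 "Supramarginal_R": "ATT",
 "Cingulum_Mid_L": "ATT",
 "Cingulum_Mid_R": "ATT",
 "Heschl_L": "AUD",
 "Heschl_R": "AUD",
 "Temporal_Sup_L": "AUD",
 "Temporal_Sup_R": "AUD",
 "Temporal_Pole_Sup_L": "AUD",
 "Temporal_Pole_Sup_R": "AUD",
 "Calcarine_L": "VIS",
 "Calcarine_R": "VIS",
 "Cuneus_L": "VIS",
 "Cuneus_R": "VIS",
 "Lingual_L": "VIS",
 "Lingual_R": "VIS",
 "Occipital_Sup_L": "VIS",
 "Occipital_Sup_R": "VIS",
 "Occipital_Mid_L": "VIS",
 "Occipital_Mid_R": "VIS",
 "Occipital_Inf_L": "VIS",
 "Occipital_Inf_R": "VIS",
 "Fusiform_L": "VIS",
 "Fusiform_R": "VIS",
 "Temporal_Inf_L": "VIS",
 "Temporal_Inf_R": "VIS",
 "Frontal_Sup_Medial_L": "DMN",
 "Frontal_Sup_Medial_R": "DMN",
 "Frontal_Med_Orb_L": "DMN",
 "Frontal_Med_Orb_R": "DMN",
 "Frontal_Mid_Orb_L": "DMN",
 "Frontal_Mid_Orb_R": "DMN",
 "Cingulum_Ant_L": "DMN",
 "Cingulum_Ant_R": "DMN",
 "Cingulum_Post_L": "DMN",
 "Cingulum_Post_R": "DMN",
 "Precuneus_L": "DMN",
 "Precuneus_R": "DMN",
 "Angular_L": "DMN",
 "Angular_R": "DMN",
 "Temporal_Mid_L": "DMN",
 "Temporal_Mid_R": "DMN",
 "Parahippocampal_L": "DMN",
 "Parahippocampal_R": "DMN",
 "Hippocampus_L": "DMN",
 "Hippocampus_R": "DMN",
 "Rectus_L": "DMN",
 "Rectus_R": "DMN",
 "Caudate_L": "SUB",
 "Caudate_R": "SUB",
 "Putamen_L": "SUB",
 "Putamen_R": "SUB",
 "Pallidum_L": "SUB",
 "Pallidum_R": "SUB",
 "Thalamus_L": "SUB",
 "Thalamus_R": "SUB",
 "Amygdala_L": "SUB",
 "Amygdala_R": "SUB",
 "Insula_L": "SUB",
 "Insula_R": "SUB",
 "Olfactory_L": "SUB",
 "Olfactory_R": "SUB"
}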