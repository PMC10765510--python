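roi,lobe
Precentral_L,frontal
Precentral_R,frontal
Frontal_Sup_L,frontal
Frontal_Sup_R,frontal
Frontal_Sup_Orb_L,frontal
Frontal_Sup_Orb_R,frontal
Frontal_Mid_L,frontal
Frontal_Mid_R,frontal
Frontal_Mid_Orb_L,frontal
Frontal_Mid_Orb_R,frontal
Frontal_Inf_Oper_L,frontal
Frontal_Inf_Oper_R,frontal
Frontal_Inf_Tri_L,frontal
Frontal_Inf_Tri_R,frontal
Frontal_Inf_Orb_L,frontal
Frontal_Inf_Orb_R,frontal
Rolandic_Oper_L,frontal
Rolandic_Oper_R,frontal
Supp_Motor_Area_L,frontal
Supp_Motor_Area_R,frontal
Olfactory_L,frontal
Olfactory_R,frontal
Frontal_Sup_Medial_L,frontal
Frontal_Sup_Medial_R,frontal
Frontal_Med_Orb_L,frontal
Frontal_Med_Orb_R,frontal
Rectus_L,frontal
Rectus_R,frontal
Cingulum_Ant_L,frontal
Cingulum_Ant_R,frontal
Cingulum_Mid_L,frontal
Cingulum_Mid_R,frontal
Paracentral_Lobule_L,frontal
Paracentral_Lobule_R,frontal
Postcentral_L,parietal
Postcentral_R,parietal
Parietal_Sup_L,parietal
Parietal_Sup_R,parietal
Parietal_Inf_L,parietal
Parietal_Inf_R,parietal
SupraMarginal_L,parietal
SupraMarginal_R,parietal
Angular_L,parietal
Angular_R,parietal
Precuneus_L,parietal
Precuneus_R,parietal
Cingulum_Post_L,parietal
Cingulum_Post_R,parietal
Calcarine_L,occipital
Calcarine_R,occipital
Cuneus_L,occipital
Cuneus_R,occipital
Lingual_L,occipital
Lingual_R,occipital
Occipital_Sup_L,occipital
Occipital_Sup_R,occipital
Occipital_Mid_L,occipital
Occipital_Mid_R,occipital
Occipital_Inf_L,occipital
Occipital_Inf_R,occipital
Hippocampus_L,temporal
Hippocampus_R,temporal
ParaHippocampal_L,temporal
ParaHippocampal_R,temporal
Amygdala_L,temporal
Amygdala_R,temporal
Fusiform_L,temporal
Fusiform_R,temporal
Heschl_L,temporal
Heschl_R,temporal
Temporal_Sup_L,temporal
Temporal_Sup_R,temporal
Temporal_Pole_Sup_L,temporal
Temporal_Pole_Sup_R,temporal
Temporal_Mid_L,temporal
Temporal_Mid_R,temporal
Temporal_Pole_Mid_L,temporal
Temporal_Pole_Mid_R,temporal
Temporal_Inf_L,temporal
Temporal_Inf_R,temporal
Insula_L,subcortical
Insula_R,subcortical
Caudate_L,subcortical
Caudate_R,subcortical
Putamen_L,subcortical
Putamen_R,subcortical
Pallidum_L,subcortical
Pallidum_R,subcortical
Thalamus_L,subcortical
Thalamus_R,subcortical
Cerebelum_Crus1_L,cerebellum
Cerebelum_Crus1_R,cerebellum
Cerebelum_Crus2_L,cerebellum
Cerebelum_Crus2_R,cerebellum
Cerebelum_3_L,cerebellum
Cerebelum_3_R,cerebellum
Cerebelum_4_5_L,cerebellum
Cerebelum_4_5_R,cerebellum
Cerebelum_6_L,cerebellum
Cerebelum_6_R,cerebellum
Cerebelum_7b_L,cerebellum
Cerebelum_7b_R,cerebellum
Cerebelum_8_L,cerebellum
Cerebelum_8_R,cerebellum
Cerebelum_9_L,cerebellum
Cerebelum_9_R,cerebellum
Cerebelum_10_L,cerebellum
Cerebelum_10_R,cerebellum
Vermis_1_2,cerebellum
Vermis_3,cerebellum
Vermis_4_5,cerebellum
Vermis_6,cerebellum
Vermis_7,cerebellum
Vermis_8,cerebellum
Vermis_9,cerebellum
Vermis_10,cerebellum
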