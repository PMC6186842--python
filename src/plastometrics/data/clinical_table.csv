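subject_id,group,lesion_side,fma_pre,fma_post,fma_6mo,age_band,gender,stroke_type,onset_years,lesion_locations
S1,guided,R,24,21,22,55-59,M,I,11,Brainstem
S2,guided,L,22,24,24,60-64,M,I,11,"PLIC, putamen"
S3,guided,R,19,34,28,45-49,M,I,1,"MFG, SFG, precentral, supramarginal, SMA"
S4,guided,L,22,27,32,65-69,M,H,8,"Insula, putamen, IFG, temporal pole"
S5,guided,R,13,16,27,65-69,M,H,1,"Insula, ITG, IOG, putamen"
S6,guided,R,17,25,25,45-49,M,H,0.67,"ITG, MTG, STG, MOG, angular, supramarginal"
S7,guided,R,16,14,18,60-64,M,I,3,"Insula, putamen, rolandic operculum, IFG"
S8,guided,L,41,36,40,50-54,M,I,1,"MFG, precentral, IFG, postcentral, insula, SFG"
S9,guided,R,36,41,48,45-49,F,I,1,"Putamen, insula"
S10,guided,L,20,24,26,45-49,M,H,2,
S11,guided,R,25,26,26,65-69,F,I,2,
S12,guided,R,23,33,,65-69,M,I,5,
S13,guided,R,25,32,,30-34,M,I,2,"Insula, STG, IFG, putamen, rolandic operculum, temporal pole"
S14,sham,L,28,33,24,55-59,M,H,5,"Insula, IFG, putamen"
S15,sham,R,20,25,21,55-59,M,I,7,"Insula, IFG, putamen, rolandic operculum, temporal pole"
S16,sham,L,24,22,22,50-54,M,I,1,"Putamen, caudate nucleus"
S17,sham,R,15,17,16,40-44,M,H,5,"Insula, rolandic operculum, IFG, STG, putamen, temporal pole"
S18,sham,R,17,20,20,40-44,M,H,3,"Insula, MTG, STG, putamen, temporal pole, rolandic operculum"
S19,sham,R,13,23,20,55-59,M,I,6,"Insula, rolandic operculum, IFG"
S20,sham,L,34,34,37,50-54,F,H,3,"Insula, rolandic operculum, putamen"
S21,sham,R,34,37,35,45-49,M,H,1,"Insula, putamen"
S22,sham,L,20,19,28,55-59,M,H,2,
S23,sham,R,33,31,50,40-44,M,I,2,
S24,sham,L,31,39,35,55-59,F,I,4,
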