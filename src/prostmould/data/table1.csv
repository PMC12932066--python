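patient,psa_ng_ml,psa_density,prostate_size_cc,pirads,lesion_volumes_cc,lesion_location,clinical_gg,mould_gg,notes
1,9.21,0.19,48.8,5,1.74,"Midgland, anterior TZ",2,4,
2,4.75,0.13,35.9,3,0.14,"Midgland, posteriormedial PZ",5,2,
3,5.34,0.2,26.2,4,0.41,"Midgland, posteriormedial PZ",2,1,
4,6.14,0.16,39.3,4,0.4,"Apex, posteriormedial PZ",2,2,"2 MRI (+) lesions, 1 not sampled on mould"
5,6.62,0.12,55.4,5,1.28,"Midgland, posteriormedial PZ",5,5,
6,5.24,0.14,36.2,5,1.14,"Apex, posterolateral PZ",2,2,
7,4.57,0.12,39.4,5,0.84;0.50,"Apex, posterolateral PZ",2,2,"2 MRI (+) lesions, mould biopsies both (+)"
8,9.68,0.36,27.2,4,0.96,"Base, posteriomedial PZ",5,3,"2 MRI lesions, only 1 (+) for cancer"
9,4.90,0.14,35.6,5,0.4,"Midgland, posterolateral PZ",2,4,
10,14.24,0.55,25.7,5,2.41,"Apex, posteriomedial PZ",4,4,
11,14.02,0.55,25.5,5,0.63;0.13,"Midgland, posterolateral PZ",2,2,"2 MRI (+) lesions, smaller 0.13 cc lesion was (−) on mould biopsy"
12,7.62,0.21,36.5,5,0.95,"Midgland, posteriomedial PZ",3,5,
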