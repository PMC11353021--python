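protocol,n_studies,n_male,n_female,age_median,age_sd,age_min,age_max,n_recurrent
ABD_PELVIS_C,1438,771,667,48.2,18.3,22,80,104
POLYTRAUMA,1038,932,106,28.0,8.5,22,34,34
KUB,723,490,233,59.0,18.7,39,76,3
BRAIN_STROKE_CTA,663,486,177,63.8,13.9,40,80,18
CHEST_ABD_PELVIS_C,357,203,154,68.5,7.9,55,80,40
TRIPHASIC_LIVER,99,54,45,56.2,13.4,34,70,29
ABD_ANGIO,88,55,33,44.3,22.7,22,75,20
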