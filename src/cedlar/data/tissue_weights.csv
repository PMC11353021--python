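set,organ,weight
ICRP-103,red_bone_marrow,0.12
ICRP-103,colon,0.12
ICRP-103,lung,0.12
ICRP-103,stomach,0.12
ICRP-103,breast,0.12
ICRP-103,gonads,0.08
ICRP-103,bladder,0.04
ICRP-103,liver,0.04
ICRP-103,esophagus,0.04
ICRP-103,thyroid,0.04
ICRP-103,skin,0.01
ICRP-103,brain,0.01
ICRP-103,salivary_glands,0.01
ICRP-103,kidneys,0.00923
ICRP-103,uterus,0.00923
ICRP-103,prostate,0.00923
ICRP-103,eye_lenses,0.0
ICRP-60,gonads,0.2
ICRP-60,red_bone_marrow,0.12
ICRP-60,colon,0.12
ICRP-60,lung,0.12
ICRP-60,stomach,0.12
ICRP-60,bladder,0.05
ICRP-60,breast,0.05
ICRP-60,liver,0.05
ICRP-60,esophagus,0.05
ICRP-60,thyroid,0.05
ICRP-60,skin,0.01
ICRP-60,kidneys,0.005
ICRP-60,brain,0.005
ICRP-60,uterus,0.005
ICRP-60,prostate,0.005
ICRP-60,salivary_glands,0.0
ICRP-60,eye_lenses,0.0
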