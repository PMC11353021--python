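kind,sex,site,age,coefficient
incidence,F,bladder,0,212
incidence,F,bladder,5,180
incidence,F,bladder,10,152
incidence,F,bladder,15,129
incidence,F,bladder,20,109
incidence,F,bladder,30,79
incidence,F,bladder,40,78
incidence,F,bladder,50,74
incidence,F,bladder,60,64
incidence,F,bladder,70,47
incidence,F,bladder,80,24
incidence,F,breast,0,1171
incidence,F,breast,5,914
incidence,F,breast,10,712
incidence,F,breast,15,553
incidence,F,breast,20,429
incidence,F,breast,30,253
incidence,F,breast,40,141
incidence,F,breast,50,70
incidence,F,breast,60,31
incidence,F,breast,70,12
incidence,F,breast,80,4
incidence,F,colon,0,220
incidence,F,colon,5,187
incidence,F,colon,10,158
incidence,F,colon,15,134
incidence,F,colon,20,114
incidence,F,colon,30,82
incidence,F,colon,40,79
incidence,F,colon,50,73
incidence,F,colon,60,62
incidence,F,colon,70,45
incidence,F,colon,80,23
incidence,F,liver,0,28
incidence,F,liver,5,23
incidence,F,liver,10,20
incidence,F,liver,15,16
incidence,F,liver,20,14
incidence,F,liver,30,10
incidence,F,liver,40,10
incidence,F,liver,50,9
incidence,F,liver,60,7
incidence,F,liver,70,5
incidence,F,liver,80,2
incidence,F,lung,0,733
incidence,F,lung,5,608
incidence,F,lung,10,504
incidence,F,lung,15,417
incidence,F,lung,20,346
incidence,F,lung,30,242
incidence,F,lung,40,240
incidence,F,lung,50,230
incidence,F,lung,60,201
incidence,F,lung,70,147
incidence,F,lung,80,77
incidence,F,stomach,0,101
incidence,F,stomach,5,85
incidence,F,stomach,10,72
incidence,F,stomach,15,61
incidence,F,stomach,20,52
incidence,F,stomach,30,36
incidence,F,stomach,40,35
incidence,F,stomach,50,32
incidence,F,stomach,60,27
incidence,F,stomach,70,19
incidence,F,stomach,80,11
incidence,F,thyroid,0,634
incidence,F,thyroid,5,419
incidence,F,thyroid,10,275
incidence,F,thyroid,15,178
incidence,F,thyroid,20,113
incidence,F,thyroid,30,41
incidence,F,thyroid,40,14
incidence,F,thyroid,50,4
incidence,F,thyroid,60,1
incidence,F,thyroid,70,0.3
incidence,F,thyroid,80,0.0
incidence,F,uterus,0,50
incidence,F,uterus,5,42
incidence,F,uterus,10,36
incidence,F,uterus,15,30
incidence,F,uterus,20,26
incidence,F,uterus,30,18
incidence,F,uterus,40,16
incidence,F,uterus,50,13
incidence,F,uterus,60,9
incidence,F,uterus,70,5
incidence,F,uterus,80,2
incidence,M,bladder,0,209
incidence,M,bladder,5,177
incidence,M,bladder,10,150
incidence,M,bladder,15,127
incidence,M,bladder,20,108
incidence,M,bladder,30,79
incidence,M,bladder,40,79
incidence,M,bladder,50,76
incidence,M,bladder,60,66
incidence,M,bladder,70,47
incidence,M,bladder,80,23
incidence,M,colon,0,336
incidence,M,colon,5,285
incidence,M,colon,10,241
incidence,M,colon,15,204
incidence,M,colon,20,173
incidence,M,colon,30,125
incidence,M,colon,40,122
incidence,M,colon,50,113
incidence,M,colon,60,94
incidence,M,colon,70,65
incidence,M,colon,80,30
incidence,M,liver,0,61
incidence,M,liver,5,50
incidence,M,liver,10,43
incidence,M,liver,15,36
incidence,M,liver,20,30
incidence,M,liver,30,22
incidence,M,liver,40,21
incidence,M,liver,50,19
incidence,M,liver,60,14
incidence,M,liver,70,8
incidence,M,liver,80,3
incidence,M,lung,0,314
incidence,M,lung,5,261
incidence,M,lung,10,216
incidence,M,lung,15,180
incidence,M,lung,20,149
incidence,M,lung,30,105
incidence,M,lung,40,104
incidence,M,lung,50,101
incidence,M,lung,60,89
incidence,M,lung,70,65
incidence,M,lung,80,34
incidence,M,prostate,0,93
incidence,M,prostate,5,80
incidence,M,prostate,10,67
incidence,M,prostate,15,57
incidence,M,prostate,20,48
incidence,M,prostate,30,35
incidence,M,prostate,40,35
incidence,M,prostate,50,33
incidence,M,prostate,60,26
incidence,M,prostate,70,14
incidence,M,prostate,80,5
incidence,M,stomach,0,76
incidence,M,stomach,5,65
incidence,M,stomach,10,55
incidence,M,stomach,15,46
incidence,M,stomach,20,40
incidence,M,stomach,30,28
incidence,M,stomach,40,27
incidence,M,stomach,50,25
incidence,M,stomach,60,20
incidence,M,stomach,70,14
incidence,M,stomach,80,7
incidence,M,thyroid,0,115
incidence,M,thyroid,5,76
incidence,M,thyroid,10,50
incidence,M,thyroid,15,33
incidence,M,thyroid,20,21
incidence,M,thyroid,30,9
incidence,M,thyroid,40,3
incidence,M,thyroid,50,1
incidence,M,thyroid,60,0.3
incidence,M,thyroid,70,0.1
incidence,M,thyroid,80,0.0
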