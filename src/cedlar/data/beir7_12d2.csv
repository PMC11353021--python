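kind,sex,site,age,coefficient
mortality,F,bladder,0,59
mortality,F,bladder,5,51
mortality,F,bladder,10,43
mortality,F,bladder,15,36
mortality,F,bladder,20,31
mortality,F,bladder,30,23
mortality,F,bladder,40,23
mortality,F,bladder,50,22
mortality,F,bladder,60,21
mortality,F,bladder,70,19
mortality,F,bladder,80,13
mortality,F,breast,0,274
mortality,F,breast,5,214
mortality,F,breast,10,167
mortality,F,breast,15,130
mortality,F,breast,20,101
mortality,F,breast,30,61
mortality,F,breast,40,35
mortality,F,breast,50,19
mortality,F,breast,60,9
mortality,F,breast,70,5
mortality,F,breast,80,2
mortality,F,colon,0,102
mortality,F,colon,5,86
mortality,F,colon,10,73
mortality,F,colon,15,62
mortality,F,colon,20,53
mortality,F,colon,30,38
mortality,F,colon,40,37
mortality,F,colon,50,35
mortality,F,colon,60,31
mortality,F,colon,70,25
mortality,F,colon,80,15
mortality,F,liver,0,24
mortality,F,liver,5,20
mortality,F,liver,10,17
mortality,F,liver,15,14
mortality,F,liver,20,12
mortality,F,liver,30,9
mortality,F,liver,40,8
mortality,F,liver,50,8
mortality,F,liver,60,7
mortality,F,liver,70,5
mortality,F,liver,80,2
mortality,F,lung,0,628
mortality,F,lung,5,534
mortality,F,lung,10,442
mortality,F,lung,15,367
mortality,F,lung,20,305
mortality,F,lung,30,213
mortality,F,lung,40,212
mortality,F,lung,50,204
mortality,F,lung,60,183
mortality,F,lung,70,140
mortality,F,lung,80,76
mortality,F,stomach,0,57
mortality,F,stomach,5,48
mortality,F,stomach,10,41
mortality,F,stomach,15,34
mortality,F,stomach,20,29
mortality,F,stomach,30,21
mortality,F,stomach,40,20
mortality,F,stomach,50,19
mortality,F,stomach,60,16
mortality,F,stomach,70,13
mortality,F,stomach,80,8
mortality,F,thyroid,0,0
mortality,F,thyroid,5,0
mortality,F,thyroid,10,0
mortality,F,thyroid,15,0
mortality,F,thyroid,20,0
mortality,F,thyroid,30,0
mortality,F,thyroid,40,0
mortality,F,thyroid,50,0
mortality,F,thyroid,60,0
mortality,F,thyroid,70,0
mortality,F,thyroid,80,0
mortality,F,uterus,0,11
mortality,F,uterus,5,10
mortality,F,uterus,10,8
mortality,F,uterus,15,7
mortality,F,uterus,20,6
mortality,F,uterus,30,4
mortality,F,uterus,40,4
mortality,F,uterus,50,3
mortality,F,uterus,60,3
mortality,F,uterus,70,2
mortality,F,uterus,80,1
mortality,M,bladder,0,45
mortality,M,bladder,5,38
mortality,M,bladder,10,32
mortality,M,bladder,15,27
mortality,M,bladder,20,23
mortality,M,bladder,30,17
mortality,M,bladder,40,17
mortality,M,bladder,50,17
mortality,M,bladder,60,17
mortality,M,bladder,70,13
mortality,M,bladder,80,8
mortality,M,colon,0,163
mortality,M,colon,5,139
mortality,M,colon,10,117
mortality,M,colon,15,99
mortality,M,colon,20,84
mortality,M,colon,30,61
mortality,M,colon,40,60
mortality,M,colon,50,57
mortality,M,colon,60,49
mortality,M,colon,70,36
mortality,M,colon,80,21
mortality,M,liver,0,44
mortality,M,liver,5,37
mortality,M,liver,10,31
mortality,M,liver,15,27
mortality,M,liver,20,23
mortality,M,liver,30,16
mortality,M,liver,40,16
mortality,M,liver,50,14
mortality,M,liver,60,12
mortality,M,liver,70,8
mortality,M,liver,80,3
mortality,M,lung,0,300
mortality,M,lung,5,255
mortality,M,lung,10,212
mortality,M,lung,15,177
mortality,M,lung,20,147
mortality,M,lung,30,104
mortality,M,lung,40,103
mortality,M,lung,50,100
mortality,M,lung,60,88
mortality,M,lung,70,64
mortality,M,lung,80,33
mortality,M,prostate,0,17
mortality,M,prostate,5,15
mortality,M,prostate,10,12
mortality,M,prostate,15,10
mortality,M,prostate,20,9
mortality,M,prostate,30,6
mortality,M,prostate,40,6
mortality,M,prostate,50,7
mortality,M,prostate,60,7
mortality,M,prostate,70,7
mortality,M,prostate,80,5
mortality,M,stomach,0,41
mortality,M,stomach,5,34
mortality,M,stomach,10,30
mortality,M,stomach,15,25
mortality,M,stomach,20,21
mortality,M,stomach,30,16
mortality,M,stomach,40,15
mortality,M,stomach,50,13
mortality,M,stomach,60,11
mortality,M,stomach,70,8
mortality,M,stomach,80,4
mortality,M,thyroid,0,0
mortality,M,thyroid,5,0
mortality,M,thyroid,10,0
mortality,M,thyroid,15,0
mortality,M,thyroid,20,0
mortality,M,thyroid,30,0
mortality,M,thyroid,40,0
mortality,M,thyroid,50,0
mortality,M,thyroid,60,0
mortality,M,thyroid,70,0
mortality,M,thyroid,80,0
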