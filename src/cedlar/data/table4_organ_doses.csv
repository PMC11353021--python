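sex,age_band,ced_median,ced_min,ced_max,organ,dose_median,dose_p25,dose_p75
M,21-30,185.75,156.7,214.8,bladder,26.6,24.17,29.02
M,21-30,185.75,156.7,214.8,colon,38.29,30.94,45.63
M,21-30,185.75,156.7,214.8,liver,45.11,34.57,55.64
M,21-30,185.75,156.7,214.8,lung,6.05,4.5,7.59
M,21-30,185.75,156.7,214.8,stomach,29.41,22.59,36.23
M,21-30,185.75,156.7,214.8,thyroid,0.8,0.67,1.08
M,21-30,185.75,156.7,214.8,prostate,29.56,26.91,32.2
M,31-40,119.2,102.9,149.9,bladder,30.05,7.57,37.13
M,31-40,119.2,102.9,149.9,colon,15.93,8.64,47.35
M,31-40,119.2,102.9,149.9,liver,16.24,9.48,49.36
M,31-40,119.2,102.9,149.9,lung,3.37,2.37,7.89
M,31-40,119.2,102.9,149.9,stomach,10.69,6.51,32.4
M,31-40,119.2,102.9,149.9,thyroid,1.14,0.37,22.9
M,31-40,119.2,102.9,149.9,prostate,16.34,8.45,37.34
M,41-50,180.55,129.4,231.7,bladder,68.43,51.12,85.74
M,41-50,180.55,129.4,231.7,colon,75.38,56.33,94.42
M,41-50,180.55,129.4,231.7,liver,77.02,57.71,96.33
M,41-50,180.55,129.4,231.7,lung,10.51,8.65,12.36
M,41-50,180.55,129.4,231.7,stomach,50.91,38.35,63.48
M,41-50,180.55,129.4,231.7,thyroid,3.64,2.91,4.36
M,41-50,180.55,129.4,231.7,prostate,75.66,56.3,95.01
M,51-60,164.9,103.3,223.0,bladder,10.74,3.36,19.51
M,51-60,164.9,103.3,223.0,colon,18.19,5.33,21.05
M,51-60,164.9,103.3,223.0,liver,21.45,7.03,35.06
M,51-60,164.9,103.3,223.0,lung,5.37,2.87,25.67
M,51-60,164.9,103.3,223.0,stomach,14.12,5.8,29.6
M,51-60,164.9,103.3,223.0,thyroid,3.48,1.26,4.28
M,51-60,164.9,103.3,223.0,prostate,8.45,2.96,21.87
M,61-70,132.0,112.3,142.9,bladder,36.87,20.83,41.06
M,61-70,132.0,112.3,142.9,colon,68.8,25.32,85.69
M,61-70,132.0,112.3,142.9,liver,98.88,27.3,134.73
M,61-70,132.0,112.3,142.9,lung,73.55,3.32,102.95
M,61-70,132.0,112.3,142.9,stomach,81.39,17.92,110.54
M,61-70,132.0,112.3,142.9,thyroid,11.46,0.5,13.8
M,61-70,132.0,112.3,142.9,prostate,22.21,21.21,34.39
M,71-80,161.4,101.9,220.9,bladder,24.95,21.58,28.33
M,71-80,161.4,101.9,220.9,colon,33.83,26.88,40.77
M,71-80,161.4,101.9,220.9,liver,47.01,34.05,59.96
M,71-80,161.4,101.9,220.9,lung,24.36,14.0,37.41
M,71-80,161.4,101.9,220.9,stomach,35.48,24.63,46.34
M,71-80,161.4,101.9,220.9,thyroid,11.44,11.32,11.57
M,71-80,161.4,101.9,220.9,prostate,25.1,23.02,27.17
M,81-90,121.9,,,bladder,36.43,,
M,81-90,121.9,,,colon,49.99,,
M,81-90,121.9,,,liver,52.73,,
M,81-90,121.9,,,lung,6.65,,
M,81-90,121.9,,,stomach,34.69,,
M,81-90,121.9,,,thyroid,2.57,,
M,81-90,121.9,,,prostate,36.94,,
F,21-30,122.5,,,bladder,31.38,,
F,21-30,122.5,,,breast,0.81,,
F,21-30,122.5,,,colon,16.91,,
F,21-30,122.5,,,liver,5.59,,
F,21-30,122.5,,,lung,1.02,,
F,21-30,122.5,,,stomach,3.87,,
F,21-30,122.5,,,thyroid,0.28,,
F,21-30,122.5,,,uterus,35.83,,
F,31-40,108.1,,,bladder,21.1,,
F,31-40,108.1,,,breast,1.54,,
F,31-40,108.1,,,colon,24.87,,
F,31-40,108.1,,,liver,25.54,,
F,31-40,108.1,,,lung,3.21,,
F,31-40,108.1,,,stomach,17.57,,
F,31-40,108.1,,,thyroid,0.53,,
F,31-40,108.1,,,uterus,18.75,,
F,41-50,,,,,,,
F,51-60,103.3,,,bladder,189.2,,
F,51-60,103.3,,,breast,13.72,,
F,51-60,103.3,,,colon,222.48,,
F,51-60,103.3,,,liver,232.44,,
F,51-60,103.3,,,lung,28.92,,
F,51-60,103.3,,,stomach,158.56,,
F,51-60,103.3,,,thyroid,4.56,,
F,51-60,103.3,,,uterus,164.62,,
F,61-70,190.1,,,bladder,24.44,,
F,61-70,190.1,,,breast,19.31,,
F,61-70,190.1,,,colon,37.26,,
F,61-70,190.1,,,liver,47.78,,
F,61-70,190.1,,,lung,22.61,,
F,61-70,190.1,,,stomach,36.41,,
F,61-70,190.1,,,thyroid,10.42,,
F,61-70,190.1,,,uterus,25.95,,
F,71-80,112.3,,,bladder,26.39,,
F,71-80,112.3,,,breast,57.58,,
F,71-80,112.3,,,colon,56.23,,
F,71-80,112.3,,,liver,72.89,,
F,71-80,112.3,,,lung,62.61,,
F,71-80,112.3,,,stomach,63.88,,
F,71-80,112.3,,,thyroid,9.87,,
F,71-80,112.3,,,uterus,41.73,,
F,81-90,,,,,,,
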