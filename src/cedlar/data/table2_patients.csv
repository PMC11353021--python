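index,sex,age_min,age_max,ced_mSv,interval_days,total_exams,ct_exams,xray_exams,history
1,M,46,46,231.7,3.0,32,11,21,Post right hemicolectomy and ileocolic anastomosis for perforated colon complicated with duodenal injury
2,M,57,57,223.0,46.3,7,4,3,Liver tumor (cholangiocarcinoma)
3,M,71,73,220.9,16.2,36,9,27,Metastatic colon cancer with liver metastases post multiple surgeries
4,M,25,26,214.8,1.7,61,7,53,Necrotizing pancreatitis
5,F,69,70,190.1,8.4,35,12,23,"Admitted with perianal abscess. Hospital course was complicated post-surgical by sepsis, intraabdominal collections"
6,M,56,57,164.9,1.7,22,6,16,Embolic superior mesenteric artery with bowel ischemia. Complicated exploratory laparotomy followed by multiple abdominal surgeries
7,M,22,22,156.7,1.2,33,5,28,Necrotizing pancreatitis
8,M,33,34,149.9,4.2,19,8,11,Necrotizing pancreatitis
9,M,62,63,142.9,11.6,21,6,15,Decompensated liver cirrhosis complicated by metastatic HCC and upper GI bleeding
10,M,62,63,132.0,36.9,10,7,3,Pancreas cancer
11,M,43,46,129.4,38.0,17,3,14,Bariatric surgery/sleeve gastrectomy complicated by leakage and abscess formation
12,F,22,23,122.5,3.0,16,3,13,Polytrauma with pelvic and femur fractures
13,M,79,81,121.9,41.3,23,7,16,"Cholangiocarcinoma, right lung adenocarcinoma post lobectomy and renal leiomyosarcoma"
14,M,34,34,121.1,2.9,8,3,5,Polytrauma with pelvic bone fractures and active pelvic bleeding
15,M,38,40,117.3,19.9,28,8,20,Decompensated liver cirrhosis complicated by bacterial peritonitis
16,M,61,61,112.3,25.0,4,2,2,Decompensated liver cirrhosis with HCC
17,F,70,72,112.3,107.2,9,3,6,Breast cancer
18,F,33,34,108.1,195.3,4,2,2,Class 3 severe obesity + DM + HTN and infertility
19,M,54,55,103.3,12.9,20,5,15,Lumbar spondylodiskitis + mediastinal lymphadenopathy
20,F,58,59,103.3,200.0,3,2,1,DM + HTN + NAFLD/NASH + small colonic polyp and internal hemorrhoids + adrenal adenoma
21,M,37,39,102.9,120.8,9,4,5,"Abdominal wall hernia, surgery complicated by abdominal wall collection"
22,M,73,76,101.9,25.2,35,12,23,Operated colon cancer + pulmonary embolism + retroperitoneal hematoma + DM and HTN
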