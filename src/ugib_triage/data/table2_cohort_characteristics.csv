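# Descriptive marginals of the 590-patient cohort (counts with printed
# percentages). 'exhaustive' = 1 where the printed categories partition the
# cohort (counts sum to 590).
variable,category,count,percent,exhaustive
gender,female,215,36.4,0
age,lt60,166,28.1,1
age,60_79,133,22.5,1
age,ge80,291,49.3,1
history,liver_disease,41,6.9,0
history,renal_disease,3,0.5,0
history,heart_disease,337,57.1,0
history,metastatic_malignancy,6,1.0,0
symptom,melena,288,48.8,1
symptom,hematemesis,147,24.9,1
symptom,hematochezia,135,22.9,1
symptom,syncope,20,3.4,1
medication,none,272,46.1,1
medication,antiplatelet,202,34.2,1
medication,anticoagulant,90,15.3,1
medication,nsaids,26,4.4,1
endoscopy_time,lt6h,233,39.5,1
endoscopy_time,6_24h,208,35.3,1
endoscopy_time,24_48h,143,24.2,1
endoscopy_time,gt48h,4,0.7,1
endoscopy_time,no_endoscopy,2,0.3,1
transfusion,no,141,23.9,1
transfusion,yes,449,76.1,1
hemostasis,none,386,65.4,1
hemostasis,endoscopic,191,32.4,1
hemostasis,radiologic,13,2.2,1
hemostasis,surgery,0,0.0,1
mortality30,survival,565,95.8,1
mortality30,death,25,4.2,1
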