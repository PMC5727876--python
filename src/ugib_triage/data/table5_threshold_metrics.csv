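# Published threshold metrics (strictly-greater cutoffs): sensitivity and
# specificity in percent to 2 d.p., predictive values to 1 d.p.
# Interventions blocks use class sizes 280/310; the 30-day mortality block
# uses 25/565.
outcome,system,cutoff,sens,spec,ppv,npv
intervention,gbs,6,93.21,13.23,49.2,68.3
intervention,gbs,7,79.64,18.06,46.8,49.6
intervention,gbs,8,75.36,52.26,58.8,70.1
intervention,gbs,9,73.57,82.90,79.5,77.6
intervention,gbs,10,61.43,86.45,80.4,71.3
intervention,gbs,11,50.71,89.68,81.6,66.8
intervention,gbs,12,36.07,90.00,76.5,60.9
intervention,mgbs,6,92.86,13.55,49.2,67.7
intervention,mgbs,7,78.93,18.06,46.5,48.7
intervention,mgbs,8,73.57,55.81,60.1,70.0
intervention,mgbs,9,70.71,89.35,85.7,77.2
intervention,mgbs,10,46.07,89.35,79.6,64.7
intervention,mgbs,11,33.21,89.68,74.4,59.8
intervention,mgbs,12,31.79,99.68,98.9,61.8
death30,pre_e_rs,2,92.0,84.07,20.4,99.6
death30,pre_e_rs,3,88.0,90.62,29.3,99.4
death30,pre_e_rs,4,88.0,97.52,61.1,99.5
death30,pre_e_rs,5,32.0,98.94,57.1,97.0
death30,pre_e_rs,6,32.0,99.12,61.5,97.1
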