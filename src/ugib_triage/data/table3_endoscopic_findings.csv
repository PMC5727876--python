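# Endoscopic diagnoses of the cohort -- descriptive fixture only; no
# computation in this package consumes it.
diagnosis,count,percent
normal,12,2.0
gastritis,89,15.1
gastric_ulcer,235,39.9
esophagitis,86,14.6
esophageal_or_fundic_varix,49,8.3
duodenitis,1,0.2
duodenal_ulcer,38,6.4
portal_gastropathy,1,0.2
mallory_weiss_syndrome,23,3.9
malignancy,25,4.2
dieulafoy_lesion,17,2.9
others,12,2.0
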