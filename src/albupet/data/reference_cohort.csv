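# Eight-subject healthy-male cohort of the first-in-human 89Zr-AlbudAb
# biodistribution study: demographics and administered radioactivity.
subject_id,age_years,weight_kg,bmi_kg_m2,administered_MBq
105,54,76.1,25.7,12.77
110,53,72.2,22.8,14.53
122,54,68.6,23.5,14.24
123,60,92.3,27.6,13.27
125,53,91.8,27.4,14.64
127,56,70.2,21.4,14.72
132,54,73.0,20.9,15.03
135,56,83.1,23.3,13.06
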