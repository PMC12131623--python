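# SYNTHETIC annual incidence rates, relative risks and case fatality
# (plausible-magnitude stand-ins for register/meta-analysis inputs)
event,sex,risk_category,population_risk,risk_is_probability,relative_risk,case_fatality
ischemic_heart_disease,male,low,0.005,0,1.0,0.1
ischemic_heart_disease,male,medium,0.005,0,1.3,0.1
ischemic_heart_disease,male,high,0.005,0,1.8,0.1
ischemic_heart_disease,female,low,0.003,0,1.0,0.1
ischemic_heart_disease,female,medium,0.003,0,1.3,0.1
ischemic_heart_disease,female,high,0.003,0,1.8,0.1
ischemic_stroke,male,low,0.003,0,1.0,0.08
ischemic_stroke,male,medium,0.003,0,1.3,0.08
ischemic_stroke,male,high,0.003,0,1.9,0.08
ischemic_stroke,female,low,0.0025,0,1.0,0.08
ischemic_stroke,female,medium,0.0025,0,1.3,0.08
ischemic_stroke,female,high,0.0025,0,1.9,0.08
hemorrhagic_stroke,male,low,0.0008,0,1.2,0.25
hemorrhagic_stroke,male,medium,0.0008,0,1.8,0.25
hemorrhagic_stroke,male,high,0.0008,0,2.4,0.25
hemorrhagic_stroke,female,low,0.0006,0,1.2,0.25
hemorrhagic_stroke,female,medium,0.0006,0,1.8,0.25
hemorrhagic_stroke,female,high,0.0006,0,2.4,0.25
liver_cirrhosis,male,low,0.0004,0,1.5,0.1
liver_cirrhosis,male,medium,0.0004,0,3.5,0.1
liver_cirrhosis,male,high,0.0004,0,8.0,0.1
liver_cirrhosis,female,low,0.0002,0,1.5,0.1
liver_cirrhosis,female,medium,0.0002,0,3.5,0.1
liver_cirrhosis,female,high,0.0002,0,8.0,0.1
chronic_pancreatitis,male,low,0.0002,0,1.3,0.05
chronic_pancreatitis,male,medium,0.0002,0,2.5,0.05
chronic_pancreatitis,male,high,0.0002,0,6.0,0.05
chronic_pancreatitis,female,low,0.0001,0,1.3,0.05
chronic_pancreatitis,female,medium,0.0001,0,2.5,0.05
chronic_pancreatitis,female,high,0.0001,0,6.0,0.05
lower_respiratory_infections,male,low,0.008,0,1.0,0.02
lower_respiratory_infections,male,medium,0.008,0,1.2,0.02
lower_respiratory_infections,male,high,0.008,0,1.5,0.02
lower_respiratory_infections,male,very_high,0.008,0,1.9,0.02
lower_respiratory_infections,female,low,0.007,0,1.0,0.02
lower_respiratory_infections,female,medium,0.007,0,1.2,0.02
lower_respiratory_infections,female,high,0.007,0,1.5,0.02
lower_respiratory_infections,female,very_high,0.007,0,1.9,0.02
transport_injuries,male,low,0.004,0,1.0,0.02
transport_injuries,male,medium,0.004,0,1.4,0.02
transport_injuries,male,high,0.004,0,2.0,0.02
transport_injuries,male,very_high,0.004,0,3.0,0.02
transport_injuries,female,low,0.003,0,1.0,0.02
transport_injuries,female,medium,0.003,0,1.4,0.02
transport_injuries,female,high,0.003,0,2.0,0.02
transport_injuries,female,very_high,0.003,0,3.0,0.02
other_injuries,male,low,0.015,0,1.0,0.01
other_injuries,male,medium,0.015,0,1.5,0.01
other_injuries,male,high,0.015,0,2.3,0.01
other_injuries,male,very_high,0.015,0,3.5,0.01
other_injuries,female,low,0.01,0,1.0,0.01
other_injuries,female,medium,0.01,0,1.5,0.01
other_injuries,female,high,0.01,0,2.3,0.01
other_injuries,female,very_high,0.01,0,3.5,0.01
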