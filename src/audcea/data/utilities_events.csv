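# Literature utility values for complication states (Beta, mean + SE)
event,utility,se,family
hemorrhagic_stroke,0.45,0.03,beta
liver_cirrhosis,0.74,0.02,beta
chronic_pancreatitis,0.34,0.07,beta
ischemic_heart_disease,0.71,0.02,beta
ischemic_stroke,0.65,0.31,beta
transport_injuries,0.68,0.07,beta
other_injuries,0.6,0.08,beta
lower_respiratory_infections,0.75,0.2,beta
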