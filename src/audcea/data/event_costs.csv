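# Complication costs in 2024 USD: direct medical and productivity per episode
# triangular: mean column is the mode; lo/hi the range. gamma: mean + sd.
event,cost_type,mean,family,lo,hi,sd
hemorrhagic_stroke,direct,26139.98,triangular,21674.03,31978.39,
liver_cirrhosis,direct,14416.73,triangular,6897.99,14416.13,
chronic_pancreatitis,direct,10080.83,triangular,9760.62,12254.49,
ischemic_heart_disease,direct,9536.14,triangular,8281.14,10963.26,
ischemic_stroke,direct,16075.14,triangular,15450.44,16383.98,
transport_injuries,direct,657.61,triangular,154.55,3261.29,
other_injuries,direct,430.57,triangular,154.55,3261.29,
lower_respiratory_infections,direct,3727.66,fixed,,,
hemorrhagic_stroke,productivity,2744.06,fixed,,,
liver_cirrhosis,productivity,15328.4,gamma,,,31654.95
chronic_pancreatitis,productivity,37186.92,gamma,,,50244.56
ischemic_heart_disease,productivity,15624.96,gamma,,,14211.32
ischemic_stroke,productivity,12066.23,triangular,8301.84,16088.81,
transport_injuries,productivity,8487.39,fixed,,,
other_injuries,productivity,7047.08,fixed,,,
lower_respiratory_infections,productivity,4233.1,gamma,,,192.42
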