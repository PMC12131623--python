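# SYNTHETIC baseline DRL occupancy per arm and sex, from the truncated-normal
# weekly-consumption model (mean/sd per arm) classified by the WHO bands
arm,sex,drl,probability
BSCT,male,low,0.474803
BSCT,male,medium,0.339082
BSCT,male,high,0.183386
BSCT,male,very_high,0.002729
BSCT,female,low,0.143159
BSCT,female,medium,0.331644
BSCT,female,high,0.339082
BSCT,female,very_high,0.186115
MET,male,low,0.453152
MET,male,medium,0.339459
MET,male,high,0.203442
MET,male,very_high,0.003947
MET,female,low,0.135805
MET,female,medium,0.317347
MET,female,high,0.339459
MET,female,very_high,0.207389
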