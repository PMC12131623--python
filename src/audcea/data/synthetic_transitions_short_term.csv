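# SYNTHETIC short-term DRL transition matrices per arm (trial stand-in)
arm,interval,from_drl,to_drl,probability
BSCT,baseline-12wk,low,low,0.92
BSCT,baseline-12wk,low,medium,0.06
BSCT,baseline-12wk,low,high,0.02
BSCT,baseline-12wk,low,very_high,0.0
BSCT,baseline-12wk,medium,low,0.45
BSCT,baseline-12wk,medium,medium,0.45
BSCT,baseline-12wk,medium,high,0.08
BSCT,baseline-12wk,medium,very_high,0.02
BSCT,baseline-12wk,high,low,0.25
BSCT,baseline-12wk,high,medium,0.4
BSCT,baseline-12wk,high,high,0.3
BSCT,baseline-12wk,high,very_high,0.05
BSCT,baseline-12wk,very_high,low,0.1
BSCT,baseline-12wk,very_high,medium,0.3
BSCT,baseline-12wk,very_high,high,0.35
BSCT,baseline-12wk,very_high,very_high,0.25
BSCT,12wk-26wk,low,low,0.9
BSCT,12wk-26wk,low,medium,0.08
BSCT,12wk-26wk,low,high,0.02
BSCT,12wk-26wk,low,very_high,0.0
BSCT,12wk-26wk,medium,low,0.3
BSCT,12wk-26wk,medium,medium,0.55
BSCT,12wk-26wk,medium,high,0.12
BSCT,12wk-26wk,medium,very_high,0.03
BSCT,12wk-26wk,high,low,0.15
BSCT,12wk-26wk,high,medium,0.35
BSCT,12wk-26wk,high,high,0.4
BSCT,12wk-26wk,high,very_high,0.1
BSCT,12wk-26wk,very_high,low,0.08
BSCT,12wk-26wk,very_high,medium,0.22
BSCT,12wk-26wk,very_high,high,0.35
BSCT,12wk-26wk,very_high,very_high,0.35
BSCT,26wk-52wk,low,low,0.9
BSCT,26wk-52wk,low,medium,0.08
BSCT,26wk-52wk,low,high,0.02
BSCT,26wk-52wk,low,very_high,0.0
BSCT,26wk-52wk,medium,low,0.25
BSCT,26wk-52wk,medium,medium,0.6
BSCT,26wk-52wk,medium,high,0.12
BSCT,26wk-52wk,medium,very_high,0.03
BSCT,26wk-52wk,high,low,0.12
BSCT,26wk-52wk,high,medium,0.33
BSCT,26wk-52wk,high,high,0.45
BSCT,26wk-52wk,high,very_high,0.1
BSCT,26wk-52wk,very_high,low,0.05
BSCT,26wk-52wk,very_high,medium,0.2
BSCT,26wk-52wk,very_high,high,0.35
BSCT,26wk-52wk,very_high,very_high,0.4
MET,baseline-12wk,low,low,0.9
MET,baseline-12wk,low,medium,0.08
MET,baseline-12wk,low,high,0.02
MET,baseline-12wk,low,very_high,0.0
MET,baseline-12wk,medium,low,0.4
MET,baseline-12wk,medium,medium,0.47
MET,baseline-12wk,medium,high,0.1
MET,baseline-12wk,medium,very_high,0.03
MET,baseline-12wk,high,low,0.2
MET,baseline-12wk,high,medium,0.4
MET,baseline-12wk,high,high,0.33
MET,baseline-12wk,high,very_high,0.07
MET,baseline-12wk,very_high,low,0.08
MET,baseline-12wk,very_high,medium,0.27
MET,baseline-12wk,very_high,high,0.37
MET,baseline-12wk,very_high,very_high,0.28
MET,12wk-26wk,low,low,0.88
MET,12wk-26wk,low,medium,0.09
MET,12wk-26wk,low,high,0.03
MET,12wk-26wk,low,very_high,0.0
MET,12wk-26wk,medium,low,0.27
MET,12wk-26wk,medium,medium,0.55
MET,12wk-26wk,medium,high,0.14
MET,12wk-26wk,medium,very_high,0.04
MET,12wk-26wk,high,low,0.12
MET,12wk-26wk,high,medium,0.35
MET,12wk-26wk,high,high,0.42
MET,12wk-26wk,high,very_high,0.11
MET,12wk-26wk,very_high,low,0.06
MET,12wk-26wk,very_high,medium,0.2
MET,12wk-26wk,very_high,high,0.36
MET,12wk-26wk,very_high,very_high,0.38
MET,26wk-52wk,low,low,0.88
MET,26wk-52wk,low,medium,0.09
MET,26wk-52wk,low,high,0.03
MET,26wk-52wk,low,very_high,0.0
MET,26wk-52wk,medium,low,0.22
MET,26wk-52wk,medium,medium,0.6
MET,26wk-52wk,medium,high,0.14
MET,26wk-52wk,medium,very_high,0.04
MET,26wk-52wk,high,low,0.1
MET,26wk-52wk,high,medium,0.33
MET,26wk-52wk,high,high,0.46
MET,26wk-52wk,high,very_high,0.11
MET,26wk-52wk,very_high,low,0.04
MET,26wk-52wk,very_high,medium,0.18
MET,26wk-52wk,very_high,high,0.36
MET,26wk-52wk,very_high,very_high,0.42
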