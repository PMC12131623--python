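# Trial-derived DRL utility means by sex and timepoint; empty utility = NA cell
# se column is a synthetic placeholder (trial SEs not published)
drl,sex,timepoint,utility,se
low,male,12wk,0.85,0.02
medium,male,12wk,0.84,0.02
high,male,12wk,0.842,0.02
very_high,male,12wk,,
low,female,12wk,0.834,0.02
medium,female,12wk,0.857,0.02
high,female,12wk,0.872,0.02
very_high,female,12wk,0.795,0.02
low,male,26wk,0.866,0.02
medium,male,26wk,0.867,0.02
high,male,26wk,0.815,0.02
very_high,male,26wk,,
low,female,26wk,0.836,0.02
medium,female,26wk,0.882,0.02
high,female,26wk,0.815,0.02
very_high,female,26wk,0.718,0.02
low,male,52wk,0.89,0.02
medium,male,52wk,0.881,0.02
high,male,52wk,0.833,0.02
very_high,male,52wk,,
low,female,52wk,0.862,0.02
medium,female,52wk,0.897,0.02
high,female,52wk,0.868,0.02
very_high,female,52wk,,
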