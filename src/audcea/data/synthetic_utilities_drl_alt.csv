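# SYNTHETIC alternative DRL utility set (anxiety-scale-derived stand-in);
# uniformly higher than the trial EQ-5D values
drl,sex,timepoint,utility,se
low,male,12wk,0.97,0.02
medium,male,12wk,0.96,0.02
high,male,12wk,0.962,0.02
very_high,male,12wk,,
low,female,12wk,0.954,0.02
medium,female,12wk,0.977,0.02
high,female,12wk,0.99,0.02
very_high,female,12wk,0.915,0.02
low,male,26wk,0.986,0.02
medium,male,26wk,0.987,0.02
high,male,26wk,0.935,0.02
very_high,male,26wk,,
low,female,26wk,0.956,0.02
medium,female,26wk,0.99,0.02
high,female,26wk,0.935,0.02
very_high,female,26wk,0.838,0.02
low,male,52wk,0.99,0.02
medium,male,52wk,0.99,0.02
high,male,52wk,0.953,0.02
very_high,male,52wk,,
low,female,52wk,0.982,0.02
medium,female,52wk,0.99,0.02
high,female,52wk,0.988,0.02
very_high,female,52wk,,
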