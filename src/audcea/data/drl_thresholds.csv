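# WHO drinking-risk-level bounds, grams pure alcohol/day, half-open (lower, upper]
sex,horizon,tier,lower_g,upper_g
female,temporary,low,0,20
female,temporary,medium,20,40
female,temporary,high,40,60
female,temporary,very_high,60,
male,temporary,low,0,40
male,temporary,medium,40,60
male,temporary,high,60,100
male,temporary,very_high,100,
female,medium_term,low,0,20
female,medium_term,medium,20,40
female,medium_term,high,40,
male,medium_term,low,0,40
male,medium_term,medium,40,60
male,medium_term,high,60,
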