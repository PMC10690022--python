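# Solved dystrophinopathy variant-type counts per country as printed in the
# source cohort report (India n=64, South Africa n=40).
country	deletion	nonsense	duplication	splice
India	60	3	0	1
South Africa	24	8	7	1
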