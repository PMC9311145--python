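group,biomarker,proportion
general_bacteria,14:0,0.08
general_bacteria,15:0,0.07
general_bacteria,16:0,0.55
general_bacteria,17:0,0.10
general_bacteria,18:0,0.20
gram_positive,i14:0,0.08
gram_positive,i15:0,0.30
gram_positive,a15:0,0.25
gram_positive,i16:0,0.15
gram_positive,i17:0,0.12
gram_positive,a17:0,0.10
gram_negative,16:1w7,0.35
gram_negative,cy17:0,0.20
gram_negative,18:1w7,0.25
gram_negative,cy19:0,0.20
fungi,18:2w6,0.45
fungi,18:1w9,0.35
fungi,18:3w3,0.20
protozoa,20:4w6,1.00
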