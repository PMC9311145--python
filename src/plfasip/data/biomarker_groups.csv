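biomarker,group
14:0,general_bacteria
15:0,general_bacteria
16:0,general_bacteria
17:0,general_bacteria
18:0,general_bacteria
i14:0,gram_positive
i15:0,gram_positive
a15:0,gram_positive
i16:0,gram_positive
i17:0,gram_positive
a17:0,gram_positive
16:1w7,gram_negative
cy17:0,gram_negative
18:1w7,gram_negative
cy19:0,gram_negative
18:1w9,fungi
18:2w6,fungi
18:3w3,fungi
20:4w6,protozoa
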