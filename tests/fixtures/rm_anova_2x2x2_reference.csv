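effect,F,df1,df2,p
time,0.5191575951886316,1.0,7.0,0.4945531167191293
condition,1.8212238534472498,1.0,7.0,0.21918185845546653
intensity,3.526459052364356,1.0,7.0,0.10248358025633397
time:condition,2.1650857184308254,1.0,7.0,0.18464990233590586
time:intensity,2.634655379344757,1.0,7.0,0.14858406081489492
condition:intensity,4.847638820074207,1.0,7.0,0.06356796984447871
time:condition:intensity,3.1263619273267e-05,1.0,7.0,0.9956947525150145
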