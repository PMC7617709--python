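Source,SS,ddof1,ddof2,MS,F,p_unc,p_GG_corr,ng2,eps
time,1.849869624046304,1,7,1.849869624046304,2.3658229788015435,0.16790655671699764,0.16790655671699764,0.0496259736307353,1.0
condition,7.440156653759925,1,7,7.440156653759925,5.777170503106067,0.047217541417400415,0.047217541417400415,0.17356565708637764,1.0
time * condition,1.4908123557807125,1,7,1.4908123557807125,0.6903947603206523,0.43345301799244307,0.43345301799244307,0.040382616168197764,1.0
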