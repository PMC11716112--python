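protein,stage,nuclear_relative_pct,nuclear_copies,nuclear_copies_sd,spot_bleach_pct,spot_bleach_pct_sd,frap_bound_pct,frap_bound_pct_sd,bound_copies,bound_copies_sd,residence_time_s,residence_time_s_sd,bound_per_mb,bound_per_mb_sd,long_term_pct,long_term_pct_sd,long_term_per_mb,long_term_per_mb_sd
SMC4,eG1,104,178281,20504,21,9,19,4,33873,7661,28,13,2.14,0.48,3,2.20,0.34,0.25
NCAPH,eG1,103,127174,14950,15,11,11,3,13989,4155,45,27,0.89,0.26,1,1.90,0.08,0.15
NCAPH2,eG1,101,25430,6712,22,9,,,,,,,,,,,,
CTCF,eG1,102,125460,21359,50,19,62,8,77785,16616,125,35,4.92,1.05,20,5.30,1.59,0.50
RAD21,eG1,63,151268,39019,41,10,53,7,80172,23233,155,32,5.07,1.47,15,3.90,1.44,0.53
STAG1,eG1,100,53480,13770,37,9,63,3,33692,8864,244,42,2.13,0.56,17,3.60,0.57,0.19
STAG2,eG1,56,102150,20097,37,9,47,5,48010,10738,108,12,3.04,0.68,3,2.90,0.19,0.19
SMC4,G1,100,174165,24018,10.0,8.5,,,,,,,,,,,,
NCAPH,G1,100,124990,18133,9,14,,,,,,,,,,,,
NCAPH2,G1,100,25597,7482,2.0,9.4,,,,,,,,,,,,
CTCF,G1,100,124206,23317,72,26,72.0,3.3,89428,17281,139,22,5.66,1.09,35.00,3.70,1.98,0.43
RAD21,G1,100,238095,56897,59,12,77.0,4.8,183333,45277,172,36,11.60,2.86,21.00,3.70,2.44,0.72
STAG1,G1,100,53482,13535,0.59,8,76.0,5.9,40646,10760,276,55,2.57,0.68,31.00,7.50,0.79,0.28
STAG2,G1,100,183408,33855,50,10,71.0,5.3,132054,26242,126,28,8.36,1.66,8.00,5.00,0.67,0.44
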