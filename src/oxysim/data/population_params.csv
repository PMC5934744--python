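scenario,neuron,I_re_Hz,k_CCK,ahp
ahp_fixed,1,292,20,True
ahp_fixed,2,292,20,True
ahp_fixed,3,292,20,True
ahp_fixed,4,292,20,True
ahp_fixed,5,292,20,True
ahp_fixed,6,292,20,True
ahp_fixed,7,292,20,True
ahp_fixed,8,292,20,True
ahp_fixed,9,292,20,True
ahp_fixed,10,292,20,True
ahp_fixed,11,292,20,True
ahp_fixed,12,292,20,True
ahp_fixed,13,292,20,True
ahp_fixed,14,292,20,True
ahp_fixed,15,292,20,True
ahp_fixed,16,292,20,True
ahp_fixed,17,292,20,True
ahp_fixed,18,292,20,True
ahp_fixed,19,292,20,True
ahp_fixed,20,292,20,True
ahp_fixed,21,292,20,True
ahp_fixed,22,292,20,True
ahp_fixed,23,292,20,True
ahp_random_rate,1,112,20,True
ahp_random_rate,2,63,20,True
ahp_random_rate,3,68,20,True
ahp_random_rate,4,92,20,True
ahp_random_rate,5,180,20,True
ahp_random_rate,6,74,20,True
ahp_random_rate,7,278,20,True
ahp_random_rate,8,488,20,True
ahp_random_rate,9,203,20,True
ahp_random_rate,10,69,20,True
ahp_random_rate,11,237,20,True
ahp_random_rate,12,279,20,True
ahp_random_rate,13,411,20,True
ahp_random_rate,14,156,20,True
ahp_random_rate,15,494,20,True
ahp_random_rate,16,383,20,True
ahp_random_rate,17,218,20,True
ahp_random_rate,18,699,20,True
ahp_random_rate,19,204,20,True
ahp_random_rate,20,1026,20,True
ahp_random_rate,21,67,20,True
ahp_random_rate,22,335,20,True
ahp_random_rate,23,574,20,True
ahp_random_rate_cck,1,112,13.9,True
ahp_random_rate_cck,2,63,7.5,True
ahp_random_rate_cck,3,68,5.6,True
ahp_random_rate_cck,4,92,55.3,True
ahp_random_rate_cck,5,180,18.0,True
ahp_random_rate_cck,6,74,12.0,True
ahp_random_rate_cck,7,278,8.2,True
ahp_random_rate_cck,8,488,5.5,True
ahp_random_rate_cck,9,203,8.0,True
ahp_random_rate_cck,10,69,8.7,True
ahp_random_rate_cck,11,237,10.5,True
ahp_random_rate_cck,12,279,16.8,True
ahp_random_rate_cck,13,411,41.0,True
ahp_random_rate_cck,14,156,14.0,True
ahp_random_rate_cck,15,494,23.4,True
ahp_random_rate_cck,16,383,41.7,True
ahp_random_rate_cck,17,218,35.1,True
ahp_random_rate_cck,18,699,2.3,True
ahp_random_rate_cck,19,204,27.3,True
ahp_random_rate_cck,20,1026,20.6,True
ahp_random_rate_cck,21,67,15.8,True
ahp_random_rate_cck,22,335,38.9,True
ahp_random_rate_cck,23,574,37.2,True
noahp_fixed,1,203.5,7,False
noahp_fixed,2,203.5,7,False
noahp_fixed,3,203.5,7,False
noahp_fixed,4,203.5,7,False
noahp_fixed,5,203.5,7,False
noahp_fixed,6,203.5,7,False
noahp_fixed,7,203.5,7,False
noahp_fixed,8,203.5,7,False
noahp_fixed,9,203.5,7,False
noahp_fixed,10,203.5,7,False
noahp_fixed,11,203.5,7,False
noahp_fixed,12,203.5,7,False
noahp_fixed,13,203.5,7,False
noahp_fixed,14,203.5,7,False
noahp_fixed,15,203.5,7,False
noahp_fixed,16,203.5,7,False
noahp_fixed,17,203.5,7,False
noahp_fixed,18,203.5,7,False
noahp_fixed,19,203.5,7,False
noahp_fixed,20,203.5,7,False
noahp_fixed,21,203.5,7,False
noahp_fixed,22,203.5,7,False
noahp_fixed,23,203.5,7,False
noahp_random_rate_cck,1,71,16.1,False
noahp_random_rate_cck,2,322,3.7,False
noahp_random_rate_cck,3,101,2.5,False
noahp_random_rate_cck,4,490,1.7,False
noahp_random_rate_cck,5,71,5.2,False
noahp_random_rate_cck,6,292,6.1,False
noahp_random_rate_cck,7,208,5.1,False
noahp_random_rate_cck,8,85,8.0,False
noahp_random_rate_cck,9,43,6.5,False
noahp_random_rate_cck,10,335,5.4,False
noahp_random_rate_cck,11,587,12.3,False
noahp_random_rate_cck,12,104,3.8,False
noahp_random_rate_cck,13,622,1.1,False
noahp_random_rate_cck,14,114,13.2,False
noahp_random_rate_cck,15,83,25.5,False
noahp_random_rate_cck,16,63,3.9,False
noahp_random_rate_cck,17,240,4.0,False
noahp_random_rate_cck,18,36,3.5,False
noahp_random_rate_cck,19,410,12.7,False
noahp_random_rate_cck,20,104,3.2,False
noahp_random_rate_cck,21,127,5.0,False
noahp_random_rate_cck,22,129,10.8,False
noahp_random_rate_cck,23,45,2.0,False
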