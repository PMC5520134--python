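population,map_nos,n,k,hd,pi,k_per_n
spain,11 12 13,19,4,0.456,0.00069,0.211
portugal,10,17,3,0.647,0.00507,0.177
italy,18 19 20,30,7,0.731,0.01029,0.233
england,4 5 6 7 8 9,57,15,0.902,0.0031,0.263
ireland,1 2 3,16,4,0.442,0.00068,0.25
hungary,16 17,13,3,0.513,0.0008,0.231
turkey,23,20,2,0.1,0.00028,0.1
bulgaria,22,11,1,0,0,0.091
canada,,3,1,,,
rhodes,24,4,2,,,
sweden,15,7,1,,,
slovenia,25,3,2,,,
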