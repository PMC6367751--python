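stratum,category,diseased,not_diseased
1,1,20,380
1,2,30,270
1,3,30,170
1,4,20,80
2,1,5,95
2,2,20,180
2,3,45,255
2,4,80,320
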