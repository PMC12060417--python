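generation,mean,sd
1,3.31,2.13
2,3.02,1.95
3,2.72,1.85
4,2.35,1.70
5,2.30,1.43
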