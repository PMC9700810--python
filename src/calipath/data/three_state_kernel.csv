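0,1,2
0.923,0.067,0.010
0.067,0.866,0.067
0.010,0.067,0.923
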