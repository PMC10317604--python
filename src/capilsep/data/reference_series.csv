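time_min,volume_ul
3,1
7,2.3
9,2.8
12,3.5
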