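analyte,input_value,output_value
WBC,7110,70
RBC,4420000,43400
HGB,12.2,0.006
HCT,39.9,0.08
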