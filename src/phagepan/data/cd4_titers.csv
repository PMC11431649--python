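round,input_pfu_ml,output_pfu_ml
1,2.0e13,3.1e7
2,2.5e10,1.2e6
3,2.9e11,9.8e7
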