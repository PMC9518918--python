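condition,weight,duration_years
episode,0.133,0.0211
amputation,0.021,lifelong
ptsd,0.133,1.0
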