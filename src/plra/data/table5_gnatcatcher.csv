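rate,value,definition
s_j,0.4314,survival from fledging to recruitment at age 1
s_a,0.5200,annual adult survival
f,2.2600,annual reproductive success
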