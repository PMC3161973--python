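stage	mogroside_v_percent
3DAF	0.057
50DAF	0.083
70DAF	2.150
85DAF	2.700
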