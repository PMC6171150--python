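aspect_category,used,available
east,2920,8704
flat,72,360
north,3246,10227
south,2991,9589
west,2917,9269
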