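group_id,virus_id
g1,HCTV-7
g1,HCTV-12
g2,HCTV-6
g2,HCTV-13
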