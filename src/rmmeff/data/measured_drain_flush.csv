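scenario_id,replicate,value_ppm,kind
8,1,59,eec
8,2,54,eec
8,3,46,eec
9,1,2.5,mean_between_markers
9,2,3.1,mean_between_markers
9,3,2,mean_between_markers
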