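scenario_id,source,low_percent,high_percent,note
2,ESIG,80,90,professional 80 / industrial 90
3,ESIG,90,95,professional 90 / industrial 95
4,TRA,75,95,LEV general
5,ESIG,80,80,all uses
6,ESIG,80,80,all uses
7,TRA,75,95,LEV general
9,ESIG,90,90,industrial
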