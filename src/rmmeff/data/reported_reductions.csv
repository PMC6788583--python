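scenario_id,baseline_id,statistic,reported_percent
2,1,min,98.0
2,1,opt,99.3
2,1,mean,98.8
4,1,min,96.5
4,1,opt,97.9
4,1,mean,97.1
5,1,min,91.9
5,1,opt,95.2
5,1,mean,93.5
6,1,min,99.3
6,1,opt,99.7
6,1,mean,99.5
7,1,min,98.6
7,1,opt,99.1
7,1,mean,98.9
9,8,min,93.2
9,8,opt,96.6
9,8,mean,95.2
6,5,min,89.6
6,5,opt,93.2
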