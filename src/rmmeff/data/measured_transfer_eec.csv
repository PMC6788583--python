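scenario_id,replicate,value_ppm,noe
1,1,454,0
1,2,424,0
1,3,410,0
1,4,430,0
1,5,553,0
2,1,5,0
2,2,8,0
2,3,4,0
2,4,5,0
2,5,6,0
3,1,,1
3,2,,1
3,3,,1
4,1,12,0
4,2,14,0
4,3,13,0
5,1,33,0
5,2,27,0
5,3,28,0
6,1,3,0
6,2,2,0
6,3,2,0
7,1,6,0
7,2,5,0
7,3,5,0
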