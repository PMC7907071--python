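e1,e2,cases,controls,source_table
0,0,30,95,2
0,1,22,16,2
1,0,175,123,2
1,1,187,36,2
0,0,42,84,3
0,1,10,27,3
1,0,257,104,3
1,1,106,53,3
0,0,7,24,4
0,1,45,87,4
1,0,70,28,4
1,1,291,131,4
0,0,41,93,5
0,1,11,18,5
1,0,270,127,5
1,1,92,32,5
0,0,38,78,6
0,1,14,33,6
1,0,222,105,6
1,1,140,52,6
0,0,48,107,7
0,1,4,4,7
1,0,329,141,7
1,1,33,18,7
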