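source_table,e1,e2,odds_ratio,ci_low,ci_high
2,0,1,4.354,2.086,9.076
2,1,0,4.505,2.866,7.084
2,1,1,16.537,10.070,21.157
3,0,1,0.741,0.329,1.669
3,1,0,4.942,3.258,7.497
3,1,1,4.000,2.461,6.502
4,0,1,1.773,0.716,4.395
4,1,0,8.571,3.586,20.487
4,1,1,7.668,3.598,16.344
5,0,1,1.386,0.603,3.187
5,1,0,4.840,3.227,7.260
5,1,1,6.521,3.858,11.024
6,0,1,0.871,0.417,1.816
6,1,0,4.359,2.820,6.739
6,1,1,5.526,3.404,8.972
7,0,1,2.229,0.552,8.997
7,1,0,5.217,3.585,7.592
7,1,1,4.087,2.144,7.788
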