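bin_lo,bin_hi,n,p5,p15,p50,p85,p95
0,0.25,,5.1,5.6,6.6,7.5,8.0
0.25,0.5,,5.8,6.3,7.3,8.3,8.8
0.5,0.75,,6.4,7.0,7.9,8.9,9.5
0.75,1,,6.9,7.5,8.4,9.4,10.0
1,1.5,,7.5,8.0,9.0,10.0,10.5
1.5,2,,8.0,8.5,9.5,10.4,11.0
2,3,,8.4,9.0,10.0,10.9,11.5
3,4,,8.8,9.4,10.4,11.3,11.9
4,5,,9.2,9.7,10.7,11.7,12.3
5,6,,9.6,10.2,11.2,12.3,12.8
6,7,,10.0,10.6,11.7,12.7,13.4
7,8,,10.0,10.7,11.8,12.9,13.6
8,9,,10.2,10.9,12.1,13.2,13.9
9,10,,10.3,11.1,12.3,13.6,14.3
10,11,,10.6,11.4,12.7,14.1,14.8
11,12,,11.1,11.9,13.3,14.6,15.4
12,13,,11.4,12.3,13.7,15.1,15.9
13,14,,11.9,12.7,14.1,15.4,16.2
14,15,,12.3,13.1,14.5,15.8,16.6
15,16,,12.5,13.4,14.8,16.1,16.9
16,17,,12.8,13.6,15.1,16.5,17.3
17,18,,13.0,13.8,15.3,16.7,17.4
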