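bin_lo,bin_hi,n,p5,p15,p50,p85,p95
0,0.25,,4.9,5.5,6.3,7.2,7.6
0.25,0.5,,5.6,6.2,7.1,7.9,8.4
0.5,0.75,,6.3,6.8,7.7,8.6,9.1
0.75,1,,6.8,7.3,8.2,9.2,9.7
1,1.5,,7.4,7.9,8.8,9.7,10.3
1.5,2,,7.9,8.4,9.3,10.2,10.8
2,3,,8.3,8.8,9.6,10.6,11.2
3,4,,8.7,9.1,10.1,11.1,11.7
4,5,,8.9,9.4,10.4,11.4,12.1
5,6,,9.3,9.8,10.8,11.9,12.6
6,7,,9.6,10.2,11.3,12.4,13.1
7,8,,9.7,10.3,11.4,12.5,13.2
8,9,,9.9,10.6,11.7,13.0,13.7
9,10,,10.4,11.1,12.3,13.6,14.4
10,11,,10.8,11.6,12.9,14.3,15.0
11,12,,11.2,12.0,13.3,14.7,15.5
12,13,,11.5,12.3,13.7,15.0,15.8
13,14,,11.8,12.6,14.0,15.3,16.1
14,15,,12.0,12.8,14.2,15.6,16.4
15,16,,12.0,12.9,14.4,15.8,16.7
16,17,,12.0,12.8,14.4,15.9,16.8
17,18,,12.1,12.9,14.5,16.1,17.1
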