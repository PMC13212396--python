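bin_lo,bin_hi,n,p5,p15,p50,p85,p95
0,0.25,322,4.9,5.5,6.4,7.3,7.9
0.25,0.5,148,5.7,6.2,7.2,8.1,8.7
0.5,0.75,141,6.4,6.9,7.9,8.8,9.3
0.75,1,113,6.9,7.5,8.4,9.3,9.8
1,1.5,248,7.5,8.0,8.9,9.8,10.4
1.5,2,220,8.0,8.5,9.4,10.3,10.8
2,3,378,8.3,8.9,9.8,10.8,11.3
3,4,379,8.7,9.2,10.2,11.2,11.8
4,5,194,9.0,9.5,10.5,11.6,12.2
5,6,180,9.4,10.0,11.0,12.1,12.7
6,7,187,9.8,10.4,11.5,12.6,13.3
7,8,168,9.8,10.4,11.6,12.7,13.4
8,9,172,10.0,10.7,11.9,13.1,13.8
9,10,194,10.3,11.0,12.3,13.6,14.4
10,11,185,10.7,11.5,12.8,14.2,14.9
11,12,157,11.1,11.9,13.3,14.7,15.5
12,13,153,11.5,12.3,13.7,15.0,15.8
13,14,155,11.9,12.6,14.0,15.4,16.1
14,15,162,12.1,12.9,14.3,15.7,16.4
15,16,220,12.1,13.0,14.5,15.9,16.8
16,17,278,12.1,13.0,14.6,16.1,17.0
17,18,257,12.3,13.2,14.8,16.3,17.2
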