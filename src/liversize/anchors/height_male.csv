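bin_lo,bin_hi,n,p5,p15,p50,p85,p95
50,60,,5.4,5.8,6.7,7.5,8.0
60,70,,6.3,6.8,7.6,8.5,9.0
70,80,,7.2,7.7,8.6,9.5,10.0
80,90,,7.9,8.5,9.4,10.3,10.8
90,100,,8.5,9.1,10.1,11.0,11.5
100,110,,9.1,9.7,10.7,11.6,12.2
110,120,,9.6,10.2,11.3,12.3,12.9
120,130,,10.1,10.7,11.8,12.9,13.5
130,140,,10.5,11.2,12.3,13.4,14.1
140,150,,11.1,11.8,13.0,14.1,14.8
150,160,,11.7,12.4,13.6,14.8,15.5
160,170,,12.3,13.1,14.4,15.6,16.3
170,180,,13.0,13.8,15.1,16.4,17.2
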