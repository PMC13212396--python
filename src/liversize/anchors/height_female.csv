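bin_lo,bin_hi,n,p5,p15,p50,p85,p95
50,60,,5.2,5.7,6.6,7.3,7.8
60,70,,6.2,6.7,7.6,8.4,8.9
70,80,,7.2,7.7,8.6,9.4,10.0
80,90,,7.9,8.4,9.3,10.2,10.8
90,100,,8.5,9.0,9.9,10.8,11.4
100,110,,9.0,9.5,10.4,11.4,12.1
110,120,,9.4,9.9,10.9,12.0,12.7
120,130,,9.8,10.4,11.5,12.6,13.3
130,140,,10.3,11.0,12.1,13.3,14.0
140,150,,11.0,11.7,12.9,14.2,14.9
150,160,,11.7,12.4,13.8,15.1,15.9
160,170,,12.3,13.2,14.6,16.0,16.8
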