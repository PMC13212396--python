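bin_lo,bin_hi,n,p5,p15,p50,p85,p95
50,60,150,5.3,5.7,6.6,7.4,7.9
60,70,196,6.2,6.7,7.6,8.5,9.0
70,80,245,7.2,7.7,8.6,9.5,10.0
80,90,315,7.9,8.4,9.4,10.3,10.8
90,100,397,8.5,9.0,10.0,10.9,11.5
100,110,274,9.0,9.6,10.5,11.5,12.1
110,120,195,9.5,10.1,11.1,12.2,12.8
120,130,223,9.9,10.6,11.6,12.7,13.4
130,140,222,10.4,11.1,12.2,13.4,14.0
140,150,180,11.0,11.7,12.9,14.1,14.9
150,160,280,11.7,12.4,13.7,15.0,15.8
160,170,320,12.4,13.2,14.5,15.9,16.7
170,180,142,13.0,13.8,15.2,16.6,17.5
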