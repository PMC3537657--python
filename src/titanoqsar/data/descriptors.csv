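code,s_vdw,v_vdw,e_hydr,logp,rf,pol
01TC,340,317,1.68,0.86,77.7,33.4
02TC,359,351,3.57,0.80,87.7,37.3
03TC,446,414,3.10,0.36,98.5,43.1
08TC,327,302,2.97,0.73,74.0,31.8
09TC,310,297,2.72,1.06,75.5,32.5
10TC,506,958,3.55,0.80,87.7,37.3
11TC,492,897,3.32,0.81,78.6,33.6
18TC,470,438,0.70,0.62,106.0,46.3
23TC,305,273,-3.02,0.51,74.6,30.4
24TC,401,361,-7.32,1.63,103.0,41.7
26TC,401,361,-7.85,1.63,103.0,41.7
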