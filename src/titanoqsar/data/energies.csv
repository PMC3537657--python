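complex_code,cd,e_cd,e_tc,e_sum,e_complex,e_int
01TC_aCD,aCD,69.35,572.70,642.05,626.0,16.08
02TC_aCD,aCD,69.35,601.41,670.76,651.1,19.67
03TC_aCD,aCD,69.35,567.76,637.11,619.1,17.97
08TC_aCD,aCD,69.35,571.92,641.27,624.8,16.43
09TC_aCD,aCD,69.35,686.73,756.08,740.3,15.79
10TC_aCD,aCD,69.35,601.53,670.88,653.8,17.04
11TC_aCD,aCD,69.35,575.11,644.46,631.6,12.88
18TC_aCD,aCD,69.35,571.08,640.43,623.4,16.98
23TC_aCD,aCD,69.35,557.15,626.50,613.3,13.19
24TC_aCD,aCD,69.35,566.55,635.90,624.0,11.90
26TC_aCD,aCD,69.35,566.44,635.79,621.5,14.28
01TC_bCD,bCD,79.80,572.70,652.50,637.9,14.64
02TC_bCD,bCD,79.80,601.41,681.21,660.1,21.11
03TC_bCD,bCD,79.80,567.76,647.56,630.8,16.73
08TC_bCD,bCD,79.80,571.92,651.72,632.2,19.51
09TC_bCD,bCD,79.80,686.73,766.53,746.0,20.50
10TC_bCD,bCD,79.80,601.53,681.33,660.8,20.49
11TC_bCD,bCD,79.80,575.11,654.91,634.9,19.97
18TC_bCD,bCD,79.80,571.08,650.88,629.1,21.76
23TC_bCD,bCD,79.80,557.15,636.95,617.3,19.68
24TC_bCD,bCD,79.80,566.55,646.35,622.0,24.32
26TC_bCD,bCD,79.80,566.44,646.24,622.6,23.65
01TC_gCD,gCD,91.29,572.70,663.99,640.2,23.78
02TC_gCD,gCD,91.29,601.41,692.70,664.3,28.36
03TC_gCD,gCD,91.29,567.76,659.05,635.6,23.44
08TC_gCD,gCD,91.29,571.92,663.21,637.1,26.09
09TC_gCD,gCD,91.29,686.73,778.02,752.4,25.61
10TC_gCD,gCD,91.29,601.53,692.82,664.2,28.59
11TC_gCD,gCD,91.29,575.11,666.40,639.6,26.83
18TC_gCD,gCD,91.29,571.08,662.37,640.9,21.43
23TC_gCD,gCD,91.29,557.15,648.44,629.3,19.10
24TC_gCD,gCD,91.29,566.55,657.84,629.7,28.12
26TC_gCD,gCD,91.29,566.44,657.73,630.4,27.34
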