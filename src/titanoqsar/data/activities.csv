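code,structure,ic50_hela,ic50_hela_sd,ic50_k562,ic50_k562_sd,ic50_femx,ic50_femx_sd,pa_hela,pa_k562,pa_femx
01TC,"M: Si; X: CH3; Y: CH=CH2; R: all H; R': all CH3",79.2,6.9,63.7,9.5,134.3,18.1,4.10,4.20,3.87
02TC,"M: Si; X: CH3; Y: H; R: all CH3; R': all CH3",108.6,8.6,59.4,8,116.3,8.7,3.96,4.23,3.93
03TC,"M: Si; X: CH3; Y: (CH2)2Si(CH3)2(CH=CH2); R: all H; R': all CH3",189,13.1,155.2,8.7,200,,3.72,3.81,3.70
08TC,"M: Si; X: CH3; Y: CH3; R: all H; R': all CH3",135,6,66,6,96,4,3.87,4.18,4.02
09TC,"M: Ge; X: CH3; Y: CH3; R: all H; R': all CH3",154,4,73,1,106,5,3.81,4.14,3.97
10TC,"M: Si; X: CH3; Y: H; R: all CH3; R': all CH3",109,9,59,8,116,9,3.96,4.23,3.94
11TC,"M: Si; X: CH3; Y: CH3; R: 3-CH3, 2,4,5-H; R': all CH3",117,3,88,4,101,9,3.93,4.06,4.00
18TC,"M: Si; X: CH3; Y: (CH2)2Si(CH=CH2)3; R: all H; R': all CH3",200,,200,,,,3.70,3.70,
23TC,"M,X,Y: none; R: 3-CH2(3-pyridinium); R': all H",114.2,57,,,,,3.94,,
24TC,"M,X,Y: none; R: 3-CH2(3-pyridinium); R': 3-CH2(3-pyridinium)",55.9,16.2,,,,,4.25,,
26TC,"M,X,Y: none; R: 3-CH2(4-pyridinium); R': 3-CH2(4-pyridinium)",10.8,0.6,,,,,4.97,,
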