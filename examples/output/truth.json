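{"beta_true": [[0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [-1.4982977995361229, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 1.553552346430939, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, -1.498776109788741], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [-1.4733912385833514, 0.0, -1.555132206476879, 0.0, 0.0, 0.0], [0.0, 0.0, -1.516911949508764, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 1.5278210067670186, 0.0], [0.0, 0.0, 0.0, 1.4329162778828495, 0.0, 1.4540918038387414], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, -1.487179521250569, 0.0, 0.0, 0.0], [0.0, -1.5289093971285312, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, -1.470216521217916, 1.5415082773317812, 0.0], [1.4838247630187653, -1.530769214255201, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, -1.586895024766587, 0.0], [0.0, 1.575172447263238, -1.5113716427605721, 1.5161587953184312, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.4360652436875607, 0.0, 0.0, 0.0], [1.490590025919344, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 1.4948709917087675], [-1.4672215453136124, 1.4986221488692182, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.555866034099999, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.4783610811669177, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, -1.5831465518620491, 0.0, 0.0, 0.0]], "s_true": [0.06315321561719327, 0.08844456949665452, 0.03420405429316145, 0.06246575142531777, 0.3205746815395355, 0.15568507752844496, 0.02634839224014754, 0.2674835933326619, 0.08926058195182111, 0.044496727570493944, 0.43867844201693357, 0.03257135822983092, 0.007030740768917375, 0.0008942833470260242, 0.07217091274677549, 0.3044932234722381, 0.18843579147119915, 0.012449094459997527, 0.29121068242240805, 0.15994082068818927, 0.1107037300643729, 0.10655136749233318, 0.025891846591569814, 0.0725304443630804, 0.0006140297958862334, 0.003406638493388973, 0.16806246897285823, 0.0029958597372400767, 0.15804907278746028, 0.060008309328199644], "alpha0_true": [6.653716025398154, 0.7260489587674701, 11.287334183219325, 264.3432548380544, 35.11109218643844, 15.839982296569497, 57.74841121261573, 36.58181394584091, 34.79041221245956, 10.799259071146246, 21.914259007551408, 25.461377052943458, 9.249210024694417, 5.223961787809922, 23.63100135674797, 63.93535147505835, 43.488540338213255, 36.17996024494874, 36.63156137494887, 444.3157832225121, 27.319281620859844, 69.83797931360812, 209.40124490442614, 21.314935022448395, 27.47202822982198, 70.00649953797675, 151.55190881119074, 29.120973092255866, 30.918467445874658, 22.303414095885945], "r_true": [0.5477941918868682, 0.5838834562299554, 0.4899348723605051, 1.1667598962081192, 0.7175285202088759, 0.37003875669813957, 3.4616360390633174, 0.6587396896490988, 0.5337889922509504, 1.8587312250805579, 1.7908975422104545, 0.5623277215139437, 0.47855174029481795, 0.606510416986687, 1.7589954810967359, 0.8558754774881977, 0.667411201390284, 0.9859139437108866, 1.8259415055354198, 0.4991866595444793, 0.8253886684806705, 0.5007051821139282, 2.962631070427789, 2.4822360007765694, 1.6089487888493126, 0.9354750608179584, 1.3903608362902486, 0.3495856246389199, 1.148220540029909, 0.5126906650882076, 0.515619388770188, 0.7030249083853501, 0.8393660509338964, 1.332570285037929, 1.4195492251798791, 1.1403512037279688, 0.6236485458857859, 1.4021312409053304, 0.9413187220001665, 1.8041948514327175]}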