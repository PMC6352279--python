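component_index,component_name,method,rmsecv,r2,n_pc
1,protocatechuic acid,SBSF,0.0125,0.9153,7
1,protocatechuic acid,GS,0.0135,0.9020,9
1,protocatechuic acid,NONE,0.0128,0.9116,5
2,chlorogenic acid,SBSF,0.154,0.8636,7
2,chlorogenic acid,GS,0.2621,0.6170,7
2,chlorogenic acid,NONE,0.2467,0.6858,8
3,caffeic acid,SBSF,0.0136,0.8712,6
3,caffeic acid,GS,0.0225,0.7230,7
3,caffeic acid,NONE,0.0161,0.8701,8
4,p-coumaric acid,SBSF,0.0014,0.9375,8
4,p-coumaric acid,GS,0.0024,0.8215,7
4,p-coumaric acid,NONE,0.0018,0.9213,9
5,ferulic acid,SBSF,0.0081,0.9134,7
5,ferulic acid,GS,0.0111,0.8394,7
5,ferulic acid,NONE,0.0113,0.8471,8
6,sesquiterpene lactones,SBSF,0.1241,0.898,5
6,sesquiterpene lactones,GS,0.1204,0.9017,6
6,sesquiterpene lactones,NONE,0.1525,0.8635,6
7,luteolin-7-glucoside,SBSF,0.0391,0.8471,8
7,luteolin-7-glucoside,GS,0.0404,0.8344,6
7,luteolin-7-glucoside,NONE,0.0347,0.8774,9
8,isoquercitrin,SBSF,0.1936,0.9099,6
8,isoquercitrin,GS,0.2561,0.817,4
8,isoquercitrin,NONE,0.2330,0.8187,10
9,apigenin-7-glucoside,SBSF,0.0729,0.9595,5
9,apigenin-7-glucoside,GS,0.0799,0.9621,5
9,apigenin-7-glucoside,NONE,0.0756,0.9616,5
10,astragalin,SBSF,0.2094,0.9508,6
10,astragalin,GS,0.1967,0.9581,5
10,astragalin,NONE,0.3840,0.8578,3
11,isorhamnetin-3-glucoside,SBSF,0.1262,0.9298,6
11,isorhamnetin-3-glucoside,GS,0.1227,0.9260,3
11,isorhamnetin-3-glucoside,NONE,0.1578,0.9069,3
12,quercetin,SBSF,0.0153,0.9390,8
12,quercetin,GS,0.0224,0.8532,8
12,quercetin,NONE,0.0239,0.8188,9
13,kaempferol,SBSF,0.0144,0.8608,6
13,kaempferol,GS,0.0140,0.8837,3
13,kaempferol,NONE,0.0122,0.9240,8
14,isorhamnetin,SBSF,0.0027,0.9085,4
14,isorhamnetin,GS,0.0027,0.9238,5
14,isorhamnetin,NONE,0.0034,0.8995,4
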