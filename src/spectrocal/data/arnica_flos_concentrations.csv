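component_index,component_name,sample,concentration_mg_g,sd
1,protocatechuic acid,A,0.020,0.006
1,protocatechuic acid,B,0.099,0.001
1,protocatechuic acid,C,0.11,0.002
1,protocatechuic acid,D,0.098,0.003
1,protocatechuic acid,E,0.080,0.007
1,protocatechuic acid,F,0.140,0.011
1,protocatechuic acid,G,0.013,0.001
1,protocatechuic acid,H,0.069,0.013
1,protocatechuic acid,I,0.120,0.010
1,protocatechuic acid,J,,
2,chlorogenic acid,A,1.48,0.10
2,chlorogenic acid,B,1.030,0.001
2,chlorogenic acid,C,1.5,
2,chlorogenic acid,D,2.06,0.17
2,chlorogenic acid,E,1.51,0.36
2,chlorogenic acid,F,1.39,0.07
2,chlorogenic acid,G,0.680,0.004
2,chlorogenic acid,H,1.66,0.87
2,chlorogenic acid,I,0.79,0.12
2,chlorogenic acid,J,1.80,0.22
3,caffeic acid,A,0.073,0.012
3,caffeic acid,B,0.066,0.001
3,caffeic acid,C,0.061,
3,caffeic acid,D,0.079,0.040
3,caffeic acid,E,0.062,0.042
3,caffeic acid,F,0.162,0.076
3,caffeic acid,G,,
3,caffeic acid,H,0.017,0.002
3,caffeic acid,I,0.03,0.02
3,caffeic acid,J,0.106,0.037
4,p-coumaric acid,A,0.064,0.005
4,p-coumaric acid,B,0.048,0.006
4,p-coumaric acid,C,0.058,
4,p-coumaric acid,D,0.050,0.005
4,p-coumaric acid,E,0.058,0.003
4,p-coumaric acid,F,0.052,0.002
4,p-coumaric acid,G,0.056,0.003
4,p-coumaric acid,H,0.045,0.001
4,p-coumaric acid,I,0.050,0.002
4,p-coumaric acid,J,,
5,ferulic acid,A,0.096,0.013
5,ferulic acid,B,0.096,0.049
5,ferulic acid,C,0.062,
5,ferulic acid,D,0.075,0.011
5,ferulic acid,E,0.062,0.013
5,ferulic acid,F,0.046,0.009
5,ferulic acid,G,0.071,0.007
5,ferulic acid,H,0.015,
5,ferulic acid,I,,
5,ferulic acid,J,0.0218,0.0130
6,sesquiterpene lactones,A,1.44,0.30
6,sesquiterpene lactones,B,1.27,0.03
6,sesquiterpene lactones,C,0.77,0.18
6,sesquiterpene lactones,D,1.15,0.15
6,sesquiterpene lactones,E,1.18,0.08
6,sesquiterpene lactones,F,1.17,0.14
6,sesquiterpene lactones,G,0.86,0.16
6,sesquiterpene lactones,H,0.25,0.06
6,sesquiterpene lactones,I,1.73,0.21
6,sesquiterpene lactones,J,0.93,0.07
7,isoquercitrin,A,1.49,0.23
7,isoquercitrin,B,1.49,0.09
7,isoquercitrin,C,1.92,0.03
7,isoquercitrin,D,0.93,0.04
7,isoquercitrin,E,1.82,0.45
7,isoquercitrin,F,2.12,0.12
7,isoquercitrin,G,1.93,0.02
7,isoquercitrin,H,1.74,0.19
7,isoquercitrin,I,0.27,0.03
7,isoquercitrin,J,,
8,apigenin-7-glucoside,A,0.37,0.03
8,apigenin-7-glucoside,B,0.71,0.005
8,apigenin-7-glucoside,C,1.21,0.08
8,apigenin-7-glucoside,D,1.11,0.03
8,apigenin-7-glucoside,E,1.00,0.22
8,apigenin-7-glucoside,F,0.8,0.095
8,apigenin-7-glucoside,G,0.66,0.01
8,apigenin-7-glucoside,H,0.1,0.02
8,apigenin-7-glucoside,I,0.17,0.0001
8,apigenin-7-glucoside,J,0.354,0.18
9,astragalin,A,0.83,0.07
9,astragalin,B,2.52,0.29
9,astragalin,C,2.5,0.001
9,astragalin,D,3.37,0.29
9,astragalin,E,2.34,0.51
9,astragalin,F,2.86,0.35
9,astragalin,G,1.58,0.02
9,astragalin,H,,
9,astragalin,I,0.44,0.03
9,astragalin,J,1.197,0.05
10,isorhamnetin-3-glucoside,A,0.43,0.08
10,isorhamnetin-3-glucoside,B,1.03,0.008
10,isorhamnetin-3-glucoside,C,1.22,0.008
10,isorhamnetin-3-glucoside,D,0.93,0.052
10,isorhamnetin-3-glucoside,E,1.833,0.376
10,isorhamnetin-3-glucoside,F,1.08,0.128
10,isorhamnetin-3-glucoside,G,0.75,0.009
10,isorhamnetin-3-glucoside,H,,
10,isorhamnetin-3-glucoside,I,0.22,0.01
10,isorhamnetin-3-glucoside,J,0.604,0.018
11,quercetin,A,0.15,0.03
11,quercetin,B,0.19,0.122
11,quercetin,C,0.11,0.021
11,quercetin,D,0.07,0.008
11,quercetin,E,0.06,0.0001
11,quercetin,F,0.1,0.061
11,quercetin,G,0.18,0.006
11,quercetin,H,1.15,0.0198
11,quercetin,I,0.03,0.01
11,quercetin,J,0.0406,0.002
12,luteolin-7-glucoside,A,0.58,0.15
12,luteolin-7-glucoside,B,0.45,0.03
12,luteolin-7-glucoside,C,0.41,0.01
12,luteolin-7-glucoside,D,0.38,0.02
12,luteolin-7-glucoside,E,0.46,0.09
12,luteolin-7-glucoside,F,0.42,0.09
12,luteolin-7-glucoside,G,0.45,0.04
12,luteolin-7-glucoside,H,,
12,luteolin-7-glucoside,I,0.33,0.004
12,luteolin-7-glucoside,J,0.204,0.008
13,kaempferol,A,0.16,0.02
13,kaempferol,B,0.15,0.02
13,kaempferol,C,0.09,0.01
13,kaempferol,D,0.18,0.02
13,kaempferol,E,0.15,0.04
13,kaempferol,F,0.17,0.007
13,kaempferol,G,0.48,
13,kaempferol,H,,
13,kaempferol,I,0.06,0.004
13,kaempferol,J,0.0995,0.004
14,isorhamnetin,A,0.028,0.016
14,isorhamnetin,B,0.022,0.004
14,isorhamnetin,C,0.025,0.01
14,isorhamnetin,D,0.026,0.011
14,isorhamnetin,E,0.035,0.018
14,isorhamnetin,F,0.033,0.002
14,isorhamnetin,G,0.053,0.004
14,isorhamnetin,H,,
14,isorhamnetin,I,0.023,0.008
14,isorhamnetin,J,0.0417,0.002
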