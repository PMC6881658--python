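no,no3_mg_l,edi_infant,edi_children,edi_teenager,edi_adults,hq_infant,hq_children,hq_teenager,hq_adults
1,12.000,0.0960,0.6800,0.4800,0.3846,0.0600,0.4250,0.3000,0.2404
2,18.500,0.1480,1.0483,0.7400,0.5929,0.0925,0.6552,0.4625,0.3706
3,24.000,0.1920,1.3600,0.9600,0.7692,0.1200,0.8500,0.6000,0.4808
4,14.000,0.1120,0.7933,0.5600,0.4487,0.0700,0.4958,0.3500,0.2804
5,9.000,0.0720,0.5100,0.3600,0.2885,0.0450,0.3188,0.2250,0.1803
6,12.000,0.0960,0.6800,0.4800,0.3846,0.0600,0.4250,0.3000,0.2404
7,13.500,0.1080,0.7650,0.5400,0.4327,0.0675,0.4781,0.3375,0.2704
8,17.500,0.1400,0.9917,0.7000,0.5609,0.0875,0.6198,0.4375,0.3506
9,15.000,0.1200,0.8500,0.6000,0.4808,0.0750,0.5313,0.3750,0.3005
10,17.000,0.1360,0.9633,0.6800,0.5449,0.0850,0.6021,0.4250,0.3405
11,20.000,0.1600,1.1333,0.8000,0.6410,0.1000,0.7083,0.5000,0.4006
12,28.000,0.2240,1.5867,1.1200,0.8974,0.1400,0.9917,0.7000,0.5609
13,14.500,0.1160,0.8217,0.5800,0.4647,0.0725,0.5135,0.3625,0.2905
14,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
15,17.600,0.1408,0.9973,0.7040,0.5641,0.0880,0.6233,0.4400,0.3526
16,14.500,0.1160,0.8217,0.5800,0.4647,0.0725,0.5135,0.3625,0.2905
17,10.000,0.0800,0.5667,0.4000,0.3205,0.0500,0.3542,0.2500,0.2003
18,6.500,0.0520,0.3683,0.2600,0.2083,0.0325,0.2302,0.1625,0.1302
19,16.500,0.1320,0.9350,0.6600,0.5288,0.0825,0.5844,0.4125,0.3305
20,15.000,0.1200,0.8500,0.6000,0.4808,0.0750,0.5313,0.3750,0.3005
21,8.500,0.0680,0.4817,0.3400,0.2724,0.0425,0.3010,0.2125,0.1703
22,6.500,0.0520,0.3683,0.2600,0.2083,0.0325,0.2302,0.1625,0.1302
23,9.000,0.0720,0.5100,0.3600,0.2885,0.0450,0.3188,0.2250,0.1803
24,18.500,0.1480,1.0483,0.7400,0.5929,0.0925,0.6552,0.4625,0.3706
25,12.000,0.0960,0.6800,0.4800,0.3846,0.0600,0.4250,0.3000,0.2404
26,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
27,16.500,0.1320,0.9350,0.6600,0.5288,0.0825,0.5844,0.4125,0.3305
28,10.000,0.0800,0.5667,0.4000,0.3205,0.0500,0.3542,0.2500,0.2003
29,13.500,0.1080,0.7650,0.5400,0.4327,0.0675,0.4781,0.3375,0.2704
30,25.000,0.2000,1.4167,1.0000,0.8013,0.1250,0.8854,0.6250,0.5008
31,12.000,0.0960,0.6800,0.4800,0.3846,0.0600,0.4250,0.3000,0.2404
32,12.000,0.0960,0.6800,0.4800,0.3846,0.0600,0.4250,0.3000,0.2404
33,13.500,0.1080,0.7650,0.5400,0.4327,0.0675,0.4781,0.3375,0.2704
34,17.000,0.1360,0.9633,0.6800,0.5449,0.0850,0.6021,0.4250,0.3405
35,49.000,0.3920,2.7767,1.9600,1.5705,0.2450,1.7354,1.2250,0.9816
36,17.000,0.1360,0.9633,0.6800,0.5449,0.0850,0.6021,0.4250,0.3405
37,19.500,0.1560,1.1050,0.7800,0.6250,0.0975,0.6906,0.4875,0.3906
38,11.500,0.0920,0.6517,0.4600,0.3686,0.0575,0.4073,0.2875,0.2304
39,15.000,0.1200,0.8500,0.6000,0.4808,0.0750,0.5313,0.3750,0.3005
40,12.500,0.1000,0.7083,0.5000,0.4006,0.0625,0.4427,0.3125,0.2504
41,18.000,0.1440,1.0200,0.7200,0.5769,0.0900,0.6375,0.4500,0.3606
42,14.500,0.1160,0.8217,0.5800,0.4647,0.0725,0.5135,0.3625,0.2905
43,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
44,15.500,0.1240,0.8783,0.6200,0.4968,0.0775,0.5490,0.3875,0.3105
45,11.500,0.0920,0.6517,0.4600,0.3686,0.0575,0.4073,0.2875,0.2304
46,14.500,0.1160,0.8217,0.5800,0.4647,0.0725,0.5135,0.3625,0.2905
47,11.000,0.0880,0.6233,0.4400,0.3526,0.0550,0.3896,0.2750,0.2204
48,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
49,15.800,0.1264,0.8953,0.6320,0.5064,0.0790,0.5596,0.3950,0.3165
50,16.500,0.1320,0.9350,0.6600,0.5288,0.0825,0.5844,0.4125,0.3305
51,6.000,0.0480,0.3400,0.2400,0.1923,0.0300,0.2125,0.1500,0.1202
52,16.000,0.1280,0.9067,0.6400,0.5128,0.0800,0.5667,0.4000,0.3205
53,15.500,0.1240,0.8783,0.6200,0.4968,0.0775,0.5490,0.3875,0.3105
54,16.000,0.1280,0.9067,0.6400,0.5128,0.0800,0.5667,0.4000,0.3205
55,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
56,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
57,10.000,0.0800,0.5667,0.4000,0.3205,0.0500,0.3542,0.2500,0.2003
58,12.500,0.1000,0.7083,0.5000,0.4006,0.0625,0.4427,0.3125,0.2504
59,23.500,0.1880,1.3317,0.9400,0.7532,0.1175,0.8323,0.5875,0.4708
60,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
61,26.500,0.2120,1.5017,1.0600,0.8494,0.1325,0.9385,0.6625,0.5308
62,8.500,0.0680,0.4817,0.3400,0.2724,0.0425,0.3010,0.2125,0.1703
63,20.500,0.1640,1.1617,0.8200,0.6571,0.1025,0.7260,0.5125,0.4107
64,14.000,0.1120,0.7933,0.5600,0.4487,0.0700,0.4958,0.3500,0.2804
65,13.000,0.1040,0.7367,0.5200,0.4167,0.0650,0.4604,0.3250,0.2604
66,12.500,0.1000,0.7083,0.5000,0.4006,0.0625,0.4427,0.3125,0.2504
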