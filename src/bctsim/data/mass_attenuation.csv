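# Mass attenuation coefficients (cm^2/g), 1-keV grid.
# Computed by the elemental mixture rule from standard photon
# cross-section compilation values (NIST/XCOM-style grids),
# log-log PCHIP interpolated; dominant-element compositions.
# Regenerate with scripts/make_physics_tables.py
energy_kev,water,adipose,glandular,skin,connective,pmma,ptfe,aluminum
10,5.3291,3.15426,4.65284,4.56568,4.53815,3.35694,6.80415,26.23
11,4.00425,2.38624,3.50034,3.43535,3.41442,2.53489,5.10371,19.7908
12,3.10713,1.86932,2.72106,2.67123,2.6549,1.98137,3.94643,15.3138
13,2.47544,1.50686,2.17289,2.13381,2.12078,1.59313,3.12883,12.1021
14,2.01602,1.24395,1.77446,1.74325,1.73265,1.31148,2.53301,9.73672
15,1.67267,1.04776,1.47681,1.45148,1.44272,1.10129,2.08729,7.955
16,1.40775,0.896095,1.24704,1.22625,1.21889,0.938845,1.74383,6.58222
17,1.2002,0.776871,1.06691,1.04965,1.04337,0.811183,1.47506,5.50805
18,1.03762,0.683385,0.925774,0.911278,0.905858,0.711097,1.26425,4.65996
19,0.910026,0.610167,0.815067,0.802749,0.798009,0.632707,1.09826,3.98424
20,0.809642,0.55292,0.7281,0.717513,0.713323,0.571399,0.967022,3.441
21,0.728004,0.506497,0.657421,0.648249,0.644511,0.521682,0.860091,2.99615
22,0.659197,0.467174,0.597785,0.589796,0.586434,0.479592,0.770229,2.62576
23,0.601039,0.433756,0.547318,0.540321,0.537272,0.443842,0.694482,2.31577
24,0.551735,0.405265,0.504481,0.498318,0.49553,0.413384,0.630424,2.05495
25,0.509809,0.380905,0.468011,0.462551,0.459984,0.387359,0.576067,1.83438
26,0.474057,0.360027,0.436877,0.432013,0.429631,0.365067,0.529793,1.64688
27,0.443493,0.342097,0.410236,0.405878,0.403653,0.345936,0.490279,1.4867
28,0.41731,0.32668,0.387397,0.38347,0.381379,0.329496,0.456448,1.34922
29,0.394847,0.313418,0.367794,0.364235,0.36226,0.315361,0.427416,1.23067
30,0.375561,0.302014,0.350959,0.347717,0.345842,0.303214,0.402461,1.128
31,0.358735,0.292059,0.336272,0.333306,0.33152,0.292616,0.380682,1.03809
32,0.343773,0.283197,0.32321,0.32049,0.318783,0.283187,0.361346,0.958583
33,0.330428,0.275276,0.311556,0.309054,0.307418,0.274765,0.344135,0.888119
34,0.318491,0.268171,0.301125,0.298818,0.297246,0.267216,0.328775,0.825544
35,0.307786,0.261775,0.291764,0.289631,0.288116,0.260427,0.315038,0.769858
36,0.298166,0.255999,0.283344,0.281365,0.279902,0.254301,0.302727,0.720202
37,0.289505,0.250768,0.275753,0.273913,0.272496,0.248759,0.291676,0.675834
38,0.281694,0.246017,0.268898,0.267181,0.265805,0.243732,0.28174,0.636117
39,0.274642,0.241691,0.262697,0.261091,0.259751,0.239161,0.272796,0.600498
40,0.268269,0.237744,0.257082,0.255573,0.254265,0.234995,0.264737,0.5685
41,0.262474,0.234132,0.251969,0.250548,0.24927,0.231189,0.257428,0.539533
42,0.257165,0.230815,0.247283,0.245943,0.244692,0.227696,0.250747,0.513107
43,0.252286,0.227757,0.242974,0.241708,0.240482,0.22448,0.244622,0.488971
44,0.24779,0.224926,0.239,0.237801,0.236599,0.221507,0.238995,0.4669
45,0.243635,0.222295,0.235324,0.234187,0.233007,0.218747,0.233813,0.446695
46,0.239787,0.219842,0.231914,0.230834,0.229674,0.216177,0.22903,0.428179
47,0.236214,0.217545,0.228742,0.227714,0.226572,0.213775,0.224606,0.411195
48,0.232888,0.215386,0.225783,0.224803,0.223678,0.21152,0.220507,0.395601
49,0.229786,0.21335,0.223016,0.222079,0.22097,0.209397,0.216701,0.381274
50,0.226885,0.211423,0.220422,0.219524,0.21843,0.20739,0.213161,0.3681
51,0.224169,0.2096,0.217987,0.217125,0.216044,0.205495,0.209858,0.355892
52,0.221621,0.207881,0.2157,0.214872,0.213803,0.203711,0.206767,0.344499
53,0.219227,0.206256,0.213548,0.212752,0.211695,0.202026,0.203872,0.333879
54,0.216973,0.204715,0.211521,0.210754,0.209707,0.200431,0.201157,0.323987
55,0.21485,0.203252,0.209606,0.208866,0.20783,0.198919,0.19861,0.314783
56,0.212845,0.201858,0.207795,0.207081,0.206055,0.197481,0.196217,0.306229
57,0.21095,0.200529,0.20608,0.205389,0.204372,0.196112,0.193969,0.298287
58,0.209156,0.199258,0.204452,0.203782,0.202774,0.194805,0.191854,0.290923
59,0.207455,0.19804,0.202905,0.202255,0.201256,0.193554,0.189863,0.284104
60,0.20584,0.196871,0.201433,0.200801,0.199809,0.192355,0.187989,0.2778
61,0.204301,0.195746,0.200026,0.199412,0.198427,0.191204,0.186212,0.271904
62,0.202827,0.194664,0.198678,0.19808,0.197103,0.190098,0.184518,0.266315
63,0.201414,0.193621,0.197384,0.196802,0.195831,0.189033,0.182899,0.261014
64,0.200058,0.192615,0.196141,0.195574,0.19461,0.188007,0.181352,0.255983
65,0.198755,0.191643,0.194945,0.194392,0.193434,0.187017,0.17987,0.251205
66,0.197501,0.190703,0.193793,0.193252,0.192301,0.186059,0.178449,0.246665
67,0.196292,0.189791,0.192681,0.192153,0.191208,0.185133,0.177086,0.242349
68,0.195126,0.188907,0.191606,0.191091,0.190151,0.184235,0.175777,0.238244
69,0.194,0.188048,0.190568,0.190064,0.18913,0.183364,0.174517,0.234338
70,0.192912,0.187213,0.189562,0.189069,0.18814,0.182518,0.173305,0.23062
71,0.191858,0.186399,0.188587,0.188104,0.187181,0.181695,0.172136,0.227079
72,0.190836,0.185606,0.18764,0.187167,0.186249,0.180893,0.171009,0.223706
73,0.189845,0.184832,0.18672,0.186257,0.185344,0.180111,0.16992,0.220492
74,0.188882,0.184076,0.185826,0.185371,0.184463,0.179348,0.168868,0.217428
75,0.187946,0.183337,0.184955,0.184509,0.183605,0.178603,0.16785,0.214507
76,0.187035,0.182612,0.184106,0.183668,0.182768,0.177873,0.166864,0.211721
77,0.186147,0.181903,0.183277,0.182847,0.181952,0.177159,0.165908,0.209063
78,0.185282,0.181206,0.182468,0.182045,0.181154,0.176459,0.16498,0.206528
79,0.184437,0.180523,0.181676,0.181261,0.180374,0.175771,0.164079,0.204109
80,0.183611,0.179851,0.180902,0.180493,0.17961,0.175097,0.163203,0.2018
81,0.182806,0.179191,0.180145,0.179743,0.178863,0.174435,0.162352,0.199588
82,0.18202,0.178545,0.179406,0.17901,0.178134,0.173787,0.161526,0.197459
83,0.181254,0.177911,0.178685,0.178294,0.177422,0.173153,0.160722,0.19541
84,0.180506,0.17729,0.17798,0.177595,0.176726,0.172532,0.159942,0.193438
85,0.179777,0.176682,0.177291,0.176912,0.176046,0.171924,0.159184,0.191541
86,0.179065,0.176085,0.176619,0.176245,0.175382,0.171328,0.158447,0.189715
87,0.178371,0.175499,0.175962,0.175592,0.174733,0.170744,0.157731,0.187958
88,0.177693,0.174925,0.17532,0.174955,0.174099,0.170171,0.157034,0.186268
89,0.177031,0.174361,0.174692,0.174331,0.173478,0.16961,0.156357,0.184641
90,0.176385,0.173808,0.174078,0.173722,0.172872,0.16906,0.155699,0.183077
91,0.175754,0.173265,0.173477,0.173126,0.172278,0.16852,0.155059,0.181571
92,0.175138,0.172732,0.17289,0.172542,0.171698,0.167991,0.154437,0.180124
93,0.174536,0.172208,0.172316,0.171972,0.17113,0.167472,0.153831,0.178732
94,0.173947,0.171694,0.171754,0.171413,0.170574,0.166962,0.153243,0.177394
95,0.173373,0.171189,0.171204,0.170867,0.17003,0.166462,0.15267,0.176108
96,0.172811,0.170693,0.170666,0.170332,0.169498,0.165971,0.152113,0.174872
97,0.172262,0.170206,0.17014,0.169808,0.168977,0.165489,0.151571,0.173685
98,0.171725,0.169727,0.169624,0.169295,0.168467,0.165016,0.151044,0.172545
99,0.171201,0.169256,0.169119,0.168793,0.167967,0.164552,0.150531,0.17145
100,0.170688,0.168793,0.168625,0.168302,0.167478,0.164095,0.150032,0.1704
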