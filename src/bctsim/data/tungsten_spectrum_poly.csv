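# Tungsten-anode bremsstrahlung fluence as per-1-keV-bin polynomials
# in tube potential V (kVp): phi(E;V) = max(0, c0 + c1*V) for E < V.
# Kramers continuum with 2.843 mm Al-equivalent inherent filtration,
# calibrated so the unfiltered 60 kVp spectrum has a 35 keV
# fluence-weighted mean energy (TASMIP-style normative table).
# Regenerate with scripts/make_physics_tables.py
energy_kev,c0,c1
10,-1.81644585e-09,1.81644585e-10
11,-2.54089661e-07,2.30990601e-08
12,-7.88665524e-06,6.57221270e-07
13,-9.27120704e-05,7.13169772e-06
14,-5.69344588e-04,4.06674706e-05
15,-2.23413005e-03,1.48942003e-04
16,-6.40572193e-03,4.00357621e-04
17,-1.46055709e-02,8.59151231e-04
18,-2.79984028e-02,1.55546682e-03
19,-4.70227908e-02,2.47488373e-03
20,-7.13403577e-02,3.56701789e-03
21,-1.00363130e-01,4.77919667e-03
22,-1.33352568e-01,6.06148036e-03
23,-1.69162324e-01,7.35488365e-03
24,-2.06640797e-01,8.61003321e-03
25,-2.44748456e-01,9.78993824e-03
26,-2.82619040e-01,1.08699631e-02
27,-3.19577946e-01,1.18362202e-02
28,-3.55133266e-01,1.26833309e-02
29,-3.88952372e-01,1.34121507e-02
30,-4.20833118e-01,1.40277706e-02
31,-4.50889025e-01,1.45448073e-02
32,-4.79254022e-01,1.49766882e-02
33,-5.05879168e-01,1.53296717e-02
34,-5.30761248e-01,1.56106249e-02
35,-5.53931096e-01,1.58266027e-02
36,-5.75443839e-01,1.59845511e-02
37,-5.95371012e-01,1.60911084e-02
38,-6.13794367e-01,1.61524833e-02
39,-6.30801126e-01,1.61743878e-02
40,-6.46480446e-01,1.61620111e-02
41,-6.61010531e-01,1.61222081e-02
42,-6.74550286e-01,1.60607211e-02
43,-6.87159220e-01,1.59804470e-02
44,-6.98895447e-01,1.58839874e-02
45,-7.09815024e-01,1.57736672e-02
46,-7.19971515e-01,1.56515547e-02
47,-7.29415712e-01,1.55194832e-02
48,-7.38195486e-01,1.53790726e-02
49,-7.46355736e-01,1.52317497e-02
50,-7.53938406e-01,1.50787681e-02
51,-7.61034050e-01,1.49222363e-02
52,-7.67715734e-01,1.47637641e-02
53,-7.73997652e-01,1.46037293e-02
54,-7.79894601e-01,1.44424926e-02
55,-7.85421661e-01,1.42803938e-02
56,-7.90593952e-01,1.41177492e-02
57,-7.95426434e-01,1.39548497e-02
58,-7.99933751e-01,1.37919612e-02
59,-8.04130116e-01,1.36293240e-02
60,-8.08029224e-01,1.34671537e-02
61,-8.11692967e-01,1.33064421e-02
62,-8.15181257e-01,1.31480848e-02
63,-8.18503861e-01,1.29921248e-02
64,-8.21669890e-01,1.28385920e-02
65,-8.24687845e-01,1.26875053e-02
66,-8.27565666e-01,1.25388737e-02
67,-8.30310769e-01,1.23926980e-02
68,-8.32930089e-01,1.22489719e-02
69,-8.35430114e-01,1.21076828e-02
70,-8.37816914e-01,1.19688131e-02
71,-8.40096179e-01,1.18323406e-02
72,-8.42273238e-01,1.16982394e-02
73,-8.44353090e-01,1.15664807e-02
74,-8.46340426e-01,1.14370328e-02
75,-8.48239649e-01,1.13098620e-02
76,-8.50054896e-01,1.11849328e-02
77,-8.51790058e-01,1.10622085e-02
78,-8.53448792e-01,1.09416512e-02
79,-8.55034540e-01,1.08232220e-02
80,-8.56550546e-01,1.07068818e-02
81,-8.58005823e-01,1.05926645e-02
82,-8.59408589e-01,1.04805925e-02
83,-8.60760683e-01,1.03706106e-02
84,-8.62063864e-01,1.02626650e-02
85,-8.63319815e-01,1.01567037e-02
86,-8.64530147e-01,1.00526761e-02
87,-8.65696399e-01,9.95053332e-03
88,-8.66820045e-01,9.85022778e-03
89,-8.67902495e-01,9.75171342e-03
90,-8.68945098e-01,9.65494553e-03
91,-8.69949146e-01,9.55988073e-03
92,-8.70915876e-01,9.46647691e-03
93,-8.71846471e-01,9.37469324e-03
94,-8.72742066e-01,9.28449006e-03
95,-8.73603745e-01,9.19582889e-03
96,-8.74432549e-01,9.10867239e-03
97,-8.75229475e-01,9.02298428e-03
98,-8.75995477e-01,8.93872936e-03
99,-8.76731470e-01,8.85587344e-03
100,-8.77438332e-01,8.77438332e-03
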