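energy_keV,mu_per_cm
1,1.223834712e+04
2,1.533995401e+03
3,4.559471840e+02
4,1.930722068e+02
5,9.930008016e+01
6,5.778059906e+01
7,3.662756093e+01
8,2.473191774e+01
9,1.753270417e+01
10,1.292128573e+01
11,9.830786828e+00
12,7.681705530e+00
13,6.140671989e+00
14,5.006594867e+00
15,4.153241372e+00
16,3.498630558e+00
17,2.987935416e+00
18,2.583538675e+00
19,2.259043192e+00
20,1.995551762e+00
21,1.779292880e+00
22,1.600068359e+00
23,1.450216046e+00
24,1.323903008e+00
25,1.216635286e+00
26,1.124912301e+00
27,1.045979608e+00
28,9.776495903e-01
29,9.181697751e-01
30,8.661250106e-01
31,8.203640005e-01
32,7.799435824e-01
33,7.440860678e-01
34,7.121462967e-01
35,6.835859846e-01
36,6.579535964e-01
37,6.348684404e-01
38,6.140080128e-01
39,5.950978636e-01
40,5.779034324e-01
41,5.622234327e-01
42,5.478844625e-01
43,5.347365907e-01
44,5.226497253e-01
45,5.115106101e-01
46,5.012203308e-01
47,4.916922347e-01
48,4.828501894e-01
49,4.746271177e-01
50,4.669637623e-01
51,4.598076392e-01
52,4.531121486e-01
53,4.468358166e-01
54,4.409416471e-01
55,4.353965656e-01
56,4.301709407e-01
57,4.252381713e-01
58,4.205743296e-01
59,4.161578512e-01
60,4.119692661e-01
61,4.079909636e-01
62,4.042069875e-01
63,4.006028563e-01
64,3.971654060e-01
65,3.938826508e-01
66,3.907436615e-01
67,3.877384577e-01
68,3.848579119e-01
69,3.820936654e-01
70,3.794380529e-01
71,3.768840356e-01
72,3.744251422e-01
73,3.720554150e-01
74,3.697693631e-01
75,3.675619194e-01
76,3.654284027e-01
77,3.633644831e-01
78,3.613661517e-01
79,3.594296925e-01
80,3.575516573e-01
81,3.557288434e-01
82,3.539582728e-01
83,3.522371741e-01
84,3.505629654e-01
85,3.489332390e-01
86,3.473457478e-01
87,3.457983929e-01
88,3.442892114e-01
89,3.428163666e-01
90,3.413781383e-01
91,3.399729140e-01
92,3.385991807e-01
93,3.372555182e-01
94,3.359405917e-01
95,3.346531461e-01
96,3.333920004e-01
97,3.321560421e-01
98,3.309442228e-01
99,3.297555537e-01
100,3.285891014e-01
101,3.274439847e-01
102,3.263193702e-01
103,3.252144701e-01
104,3.241285386e-01
105,3.230608696e-01
106,3.220107938e-01
107,3.209776766e-01
108,3.199609159e-01
109,3.189599400e-01
110,3.179742058e-01
111,3.170031972e-01
112,3.160464230e-01
113,3.151034161e-01
114,3.141737314e-01
115,3.132569451e-01
116,3.123526529e-01
117,3.114604695e-01
118,3.105800270e-01
119,3.097109741e-01
120,3.088529752e-01
121,3.080057096e-01
122,3.071688705e-01
123,3.063421643e-01
124,3.055253103e-01
125,3.047180390e-01
126,3.039200929e-01
127,3.031312244e-01
128,3.023511966e-01
129,3.015797819e-01
130,3.008167617e-01
131,3.000619262e-01
132,2.993150739e-01
133,2.985760107e-01
134,2.978445502e-01
135,2.971205131e-01
136,2.964037265e-01
137,2.956940243e-01
138,2.949912461e-01
139,2.942952375e-01
140,2.936058495e-01
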