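energy_keV,mass_attenuation_cm2_g
1,2.030117030e+05
2,2.540107260e+04
3,7.533608674e+03
4,3.181394204e+03
5,1.630519334e+03
6,9.445621955e+02
7,5.954568653e+02
8,3.993449964e+02
9,2.807889311e+02
10,2.049340663e+02
11,1.541565107e+02
12,1.188893160e+02
13,9.363230770e+01
14,7.506978017e+01
15,6.112161544e+01
16,5.043772428e+01
17,4.211574968e+01
18,3.553695505e+01
19,3.026741951e+01
20,2.599669681e+01
21,2.249868425e+01
22,1.960604833e+01
23,1.719314369e+01
24,1.516437916e+01
25,1.344615170e+01
26,1.198116309e+01
27,1.072435553e+01
28,9.639965382e+00
29,8.699360456e+00
30,7.879433979e+00
31,7.161399052e+00
32,6.529874663e+00
33,5.972186237e+00
34,3.076272084e+01
35,2.821698212e+01
36,2.594598761e+01
37,2.391363349e+01
38,2.208936378e+01
39,2.044720056e+01
40,1.896496327e+01
41,1.762363648e+01
42,1.640685521e+01
43,1.530048370e+01
44,1.429226898e+01
45,1.337155465e+01
46,1.252904332e+01
47,1.175659862e+01
48,1.104707947e+01
49,1.039420090e+01
50,9.792416602e+00
51,9.236819630e+00
52,8.723058001e+00
53,8.247262825e+00
54,7.805986872e+00
55,7.396151908e+00
56,7.015003419e+00
57,6.660071571e+00
58,6.329137462e+00
59,6.020203873e+00
60,5.731469847e+00
61,5.461308548e+00
62,5.208247929e+00
63,4.970953819e+00
64,4.748215081e+00
65,4.538930580e+00
66,4.342097692e+00
67,4.156802175e+00
68,3.982209211e+00
69,3.817555466e+00
70,3.662142051e+00
71,3.515328259e+00
72,3.376525993e+00
73,3.245194791e+00
74,3.120837384e+00
75,3.002995722e+00
76,2.891247408e+00
77,2.785202507e+00
78,2.684500666e+00
79,2.588808532e+00
80,2.497817415e+00
81,2.411241191e+00
82,2.328814396e+00
83,2.250290508e+00
84,2.175440385e+00
85,2.104050857e+00
86,2.035923434e+00
87,1.970873150e+00
88,1.908727489e+00
89,1.849325425e+00
90,1.792516536e+00
91,1.738160199e+00
92,1.686124852e+00
93,1.636287320e+00
94,1.588532198e+00
95,1.542751285e+00
96,1.498843064e+00
97,1.456712226e+00
98,1.416269230e+00
99,1.377429901e+00
100,1.340115057e+00
101,1.304250168e+00
102,1.269765040e+00
103,1.236593523e+00
104,1.204673240e+00
105,1.173945342e+00
106,1.144354274e+00
107,1.115847562e+00
108,1.088375619e+00
109,1.061891556e+00
110,1.036351016e+00
111,1.011712014e+00
112,9.879347905e-01
113,9.649816765e-01
114,9.428169642e-01
115,9.214067900e-01
116,9.007190241e-01
117,8.807231675e-01
118,8.613902566e-01
119,8.426927732e-01
120,8.246045614e-01
121,8.071007494e-01
122,7.901576764e-01
123,7.737528243e-01
124,7.578647542e-01
125,7.424730458e-01
126,7.275582418e-01
127,7.131017954e-01
128,6.990860206e-01
129,6.854940459e-01
130,6.723097712e-01
131,6.595178268e-01
132,6.471035345e-01
133,6.350528725e-01
134,6.233524404e-01
135,6.119894280e-01
136,6.009515847e-01
137,5.902271916e-01
138,5.798050341e-01
139,5.696743776e-01
140,5.598249429e-01
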