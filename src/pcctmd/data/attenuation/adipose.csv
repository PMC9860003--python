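energy_keV,mu_per_cm
1,2.528162017e+03
2,3.173212269e+02
3,9.449909153e+01
4,4.012656501e+01
5,2.071717310e+01
6,1.211712819e+01
7,7.732439003e+00
8,5.264799743e+00
9,3.770213784e+00
10,2.812068931e+00
11,2.169367429e+00
12,1.722019118e+00
13,1.400911514e+00
14,1.164338437e+00
15,9.861086764e-01
16,8.492056579e-01
17,7.422444835e-01
18,6.574107296e-01
19,5.892185774e-01
20,5.337392555e-01
21,4.881084853e-01
22,4.502043347e-01
23,4.184319006e-01
24,3.915765491e-01
25,3.687020917e-01
26,3.490789868e-01
27,3.321329578e-01
28,3.174077196e-01
29,3.045375979e-01
30,2.932271814e-01
31,2.832360382e-01
32,2.743671188e-01
33,2.664578761e-01
34,2.593734048e-01
35,2.530010986e-01
36,2.472464566e-01
37,2.420297687e-01
38,2.372834774e-01
39,2.329500646e-01
40,2.289803483e-01
41,2.253321032e-01
42,2.219689350e-01
43,2.188593597e-01
44,2.159760449e-01
45,2.132951827e-01
46,2.107959684e-01
47,2.084601662e-01
48,2.062717445e-01
49,2.042165702e-01
50,2.022821499e-01
51,2.004574113e-01
52,1.987325166e-01
53,1.970987043e-01
54,1.955481532e-01
55,1.940738660e-01
56,1.926695688e-01
57,1.913296251e-01
58,1.900489605e-01
59,1.888229979e-01
60,1.876476010e-01
61,1.865190251e-01
62,1.854338740e-01
63,1.843890624e-01
64,1.833817826e-01
65,1.824094755e-01
66,1.814698051e-01
67,1.805606356e-01
68,1.796800114e-01
69,1.788261392e-01
70,1.779973726e-01
71,1.771921976e-01
72,1.764092202e-01
73,1.756471554e-01
74,1.749048168e-01
75,1.741811081e-01
76,1.734750148e-01
77,1.727855969e-01
78,1.721119826e-01
79,1.714533623e-01
80,1.708089835e-01
81,1.701781458e-01
82,1.695601966e-01
83,1.689545275e-01
84,1.683605703e-01
85,1.677777942e-01
86,1.672057026e-01
87,1.666438304e-01
88,1.660917418e-01
89,1.655490281e-01
90,1.650153054e-01
91,1.644902127e-01
92,1.639734109e-01
93,1.634645802e-01
94,1.629634198e-01
95,1.624696456e-01
96,1.619829896e-01
97,1.615031986e-01
98,1.610300333e-01
99,1.605632671e-01
100,1.601026858e-01
101,1.596480859e-01
102,1.591992748e-01
103,1.587560696e-01
104,1.583182965e-01
105,1.578857905e-01
106,1.574583944e-01
107,1.570359588e-01
108,1.566183413e-01
109,1.562054061e-01
110,1.557970239e-01
111,1.553930711e-01
112,1.549934298e-01
113,1.545979871e-01
114,1.542066352e-01
115,1.538192711e-01
116,1.534357958e-01
117,1.530561149e-01
118,1.526801375e-01
119,1.523077766e-01
120,1.519389488e-01
121,1.515735738e-01
122,1.512115746e-01
123,1.508528771e-01
124,1.504974101e-01
125,1.501451049e-01
126,1.497958955e-01
127,1.494497184e-01
128,1.491065121e-01
129,1.487662175e-01
130,1.484287777e-01
131,1.480941373e-01
132,1.477622434e-01
133,1.474330443e-01
134,1.471064905e-01
135,1.467825338e-01
136,1.464611277e-01
137,1.461422271e-01
138,1.458257885e-01
139,1.455117696e-01
140,1.452001293e-01
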