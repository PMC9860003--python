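energy_keV,mass_attenuation_cm2_g
1,3.669160815e+05
2,4.589628770e+04
3,1.360838692e+04
4,5.745085294e+03
5,2.943586114e+03
6,1.704702669e+03
7,1.074311648e+03
8,7.202509898e+02
9,5.062489507e+02
10,3.693506911e+02
11,2.777272530e+02
12,2.141025289e+02
13,1.685453368e+02
14,1.350694579e+02
15,1.099198328e+02
16,9.065952790e+01
17,7.565995228e+01
18,6.380452067e+01
19,5.431025575e+01
20,4.661704192e+01
21,4.031698299e+01
22,3.510823709e+01
23,3.076418551e+01
24,2.711243512e+01
25,2.402026159e+01
26,2.138435334e+01
27,1.912347771e+01
28,1.717316506e+01
29,1.548180693e+01
30,1.400775869e+01
31,1.271716498e+01
32,1.158231109e+01
33,1.058036146e+01
34,9.692385897e+00
35,8.902601840e+00
36,8.197780041e+00
37,7.566775192e+00
38,7.000152633e+00
39,6.489889588e+00
40,6.029134584e+00
41,5.612012621e+00
42,5.233466521e+00
43,4.889127078e+00
44,4.575206245e+00
45,4.288408872e+00
46,4.025859441e+00
47,3.785040984e+00
48,3.563743971e+00
49,3.360023346e+00
50,3.172162302e+00
51,1.571357797e+01
52,1.483351232e+01
53,1.401852428e+01
54,1.326270365e+01
55,1.256077294e+01
56,1.190800974e+01
57,1.130017978e+01
58,1.073347905e+01
59,1.020448363e+01
60,9.710106140e+00
61,9.247557711e+00
62,8.814314890e+00
63,8.408090609e+00
64,8.026808746e+00
65,7.668581771e+00
66,7.331691052e+00
67,7.014569483e+00
68,6.715786120e+00
69,6.434032573e+00
70,6.168110935e+00
71,5.916923043e+00
72,5.679460923e+00
73,5.454798262e+00
74,5.242082793e+00
75,5.040529478e+00
76,4.849414401e+00
77,4.668069287e+00
78,4.495876575e+00
79,4.332264978e+00
80,4.176705498e+00
81,4.028707805e+00
82,3.887816989e+00
83,3.753610604e+00
84,3.625695998e+00
85,3.503707890e+00
86,3.387306169e+00
87,3.276173891e+00
88,3.170015463e+00
89,3.068554978e+00
90,2.971534705e+00
91,2.878713707e+00
92,2.789866575e+00
93,2.704782276e+00
94,2.623263093e+00
95,2.545123654e+00
96,2.470190041e+00
97,2.398298975e+00
98,2.329297064e+00
99,2.263040109e+00
100,2.199392469e+00
101,2.138226473e+00
102,2.079421881e+00
103,2.022865382e+00
104,1.968450133e+00
105,1.916075333e+00
106,1.865645826e+00
107,1.817071738e+00
108,1.770268137e+00
109,1.725154717e+00
110,1.681655509e+00
111,1.639698609e+00
112,1.599215927e+00
113,1.560142952e+00
114,1.522418534e+00
115,1.485984684e+00
116,1.450786382e+00
117,1.416771403e+00
118,1.383890151e+00
119,1.352095507e+00
120,1.321342686e+00
121,1.291589103e+00
122,1.262794245e+00
123,1.234919562e+00
124,1.207928346e+00
125,1.181785638e+00
126,1.156458128e+00
127,1.131914066e+00
128,1.108123174e+00
129,1.085056573e+00
130,1.062686701e+00
131,1.040987250e+00
132,1.019933096e+00
133,9.995002381e-01
134,9.796657409e-01
135,9.604076792e-01
136,9.417050864e-01
137,9.235379062e-01
138,9.058869466e-01
139,8.887338368e-01
140,8.720609865e-01
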