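energy_keV,mu_per_cm
1,3.370133591e+03
2,4.229532359e+02
3,1.259316406e+02
4,5.345629913e+01
5,2.758587489e+01
6,1.612355575e+01
7,1.027983375e+01
8,6.991244486e+00
9,4.999545108e+00
10,3.722794555e+00
11,2.866442033e+00
12,2.270432623e+00
13,1.842656197e+00
14,1.527529921e+00
15,1.290148991e+00
16,1.107836117e+00
17,9.654194817e-01
18,8.524856312e-01
19,7.617243742e-01
20,6.879005093e-01
21,6.271973960e-01
22,5.767876370e-01
23,5.345461352e-01
24,4.988545156e-01
25,4.684654346e-01
26,4.424069024e-01
27,4.199138130e-01
28,4.003782757e-01
29,3.833131299e-01
30,3.683248324e-01
31,3.550930911e-01
32,3.433554137e-01
33,3.328952752e-01
34,3.235329771e-01
35,3.151185284e-01
36,3.075260587e-01
37,3.006494015e-01
38,2.943985795e-01
39,2.886969892e-01
40,2.834791322e-01
41,2.786887761e-01
42,2.742774564e-01
43,2.702032489e-01
44,2.664297594e-01
45,2.629252882e-01
46,2.596621356e-01
47,2.566160233e-01
48,2.537656091e-01
49,2.510920789e-01
50,2.485788027e-01
51,2.462110427e-01
52,2.439757055e-01
53,2.418611308e-01
54,2.398569105e-01
55,2.379537337e-01
56,2.361432528e-01
57,2.344179688e-01
58,2.327711312e-01
59,2.311966517e-01
60,2.296890288e-01
61,2.282432826e-01
62,2.268548969e-01
63,2.255197693e-01
64,2.242341674e-01
65,2.229946896e-01
66,2.217982309e-01
67,2.206419531e-01
68,2.195232578e-01
69,2.184397629e-01
70,2.173892812e-01
71,2.163698021e-01
72,2.153794748e-01
73,2.144165931e-01
74,2.134795825e-01
75,2.125669882e-01
76,2.116774639e-01
77,2.108097629e-01
78,2.099627291e-01
79,2.091352890e-01
80,2.083264451e-01
81,2.075352691e-01
82,2.067608967e-01
83,2.060025218e-01
84,2.052593922e-01
85,2.045308052e-01
86,2.038161034e-01
87,2.031146719e-01
88,2.024259341e-01
89,2.017493496e-01
90,2.010844110e-01
91,2.004306416e-01
92,1.997875933e-01
93,1.991548442e-01
94,1.985319969e-01
95,1.979186768e-01
96,1.973145305e-01
97,1.967192244e-01
98,1.961324429e-01
99,1.955538878e-01
100,1.949832769e-01
101,1.944203426e-01
102,1.938648315e-01
103,1.933165030e-01
104,1.927751290e-01
105,1.922404925e-01
106,1.917123874e-01
107,1.911906174e-01
108,1.906749959e-01
109,1.901653450e-01
110,1.896614951e-01
111,1.891632844e-01
112,1.886705586e-01
113,1.881831701e-01
114,1.877009780e-01
115,1.872238476e-01
116,1.867516498e-01
117,1.862842611e-01
118,1.858215633e-01
119,1.853634428e-01
120,1.849097909e-01
121,1.844605032e-01
122,1.840154794e-01
123,1.835746232e-01
124,1.831378419e-01
125,1.827050466e-01
126,1.822761514e-01
127,1.818510739e-01
128,1.814297345e-01
129,1.810120565e-01
130,1.805979662e-01
131,1.801873923e-01
132,1.797802657e-01
133,1.793765203e-01
134,1.789760916e-01
135,1.785789178e-01
136,1.781849386e-01
137,1.777940962e-01
138,1.774063342e-01
139,1.770215983e-01
140,1.766398358e-01
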