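energy_keV,mu_per_cm
1,4.451482394e+04
2,5.570377936e+03
3,1.652440700e+03
4,6.980583781e+02
5,3.579582949e+02
6,2.075243924e+02
7,1.309602535e+02
8,8.794772369e+01
9,6.194374939e+01
10,4.530473465e+01
11,3.416568011e+01
12,2.642846218e+01
13,2.088681213e+01
14,1.681353050e+01
15,1.375239605e+01
16,1.140729406e+01
17,9.580306282e+00
18,8.135719132e+00
19,6.978354287e+00
20,6.040115367e+00
21,5.271405588e+00
22,4.635518628e+00
23,4.104892234e+00
24,3.658556492e+00
25,3.280364661e+00
26,2.957746566e+00
27,2.680817109e+00
28,2.441730011e+00
29,2.234203415e+00
30,2.053167593e+00
31,1.894500505e+00
32,1.754827301e+00
33,1.631366888e+00
34,1.521813480e+00
35,1.424244417e+00
36,1.337047864e+00
37,1.258865696e+00
38,1.188548074e+00
39,1.125117092e+00
40,1.067737489e+00
41,1.015692942e+00
42,9.683667469e-01
43,9.252260146e-01
44,8.858086643e-01
45,8.497126769e-01
46,8.165871730e-01
47,7.861249741e-01
48,7.580563764e-01
49,7.321439186e-01
50,7.081779680e-01
51,6.859729849e-01
52,6.653643493e-01
53,6.462056564e-01
54,6.283664054e-01
55,6.117300167e-01
56,5.961921276e-01
57,5.816591221e-01
58,5.680468599e-01
59,5.552795737e-01
60,5.432889121e-01
61,5.320131044e-01
62,5.213962320e-01
63,5.113875904e-01
64,5.019411294e-01
65,4.930149611e-01
66,4.845709268e-01
67,4.765742143e-01
68,4.689930193e-01
69,4.617982463e-01
70,4.549632418e-01
71,4.484635586e-01
72,4.422767441e-01
73,4.363821533e-01
74,4.307607800e-01
75,4.253951068e-01
76,4.202689703e-01
77,4.153674403e-01
78,4.106767104e-01
79,4.061840007e-01
80,4.018774692e-01
81,3.977461321e-01
82,3.937797920e-01
83,3.899689723e-01
84,3.863048584e-01
85,3.827792440e-01
86,3.793844823e-01
87,3.761134420e-01
88,3.729594668e-01
89,3.699163385e-01
90,3.669782437e-01
91,3.641397433e-01
92,3.613957441e-01
93,3.587414736e-01
94,3.561724560e-01
95,3.536844914e-01
96,3.512736354e-01
97,3.489361813e-01
98,3.466686432e-01
99,3.444677411e-01
100,3.423303859e-01
101,3.402536673e-01
102,3.382348411e-01
103,3.362713184e-01
104,3.343606553e-01
105,3.325005433e-01
106,3.306888007e-01
107,3.289233641e-01
108,3.272022812e-01
109,3.255237039e-01
110,3.238858812e-01
111,3.222871539e-01
112,3.207259484e-01
113,3.192007717e-01
114,3.177102069e-01
115,3.162529080e-01
116,3.148275960e-01
117,3.134330554e-01
118,3.120681296e-01
119,3.107317183e-01
120,3.094227739e-01
121,3.081402988e-01
122,3.068833419e-01
123,3.056509971e-01
124,3.044423997e-01
125,3.032567250e-01
126,3.020931856e-01
127,3.009510296e-01
128,2.998295385e-01
129,2.987280259e-01
130,2.976458353e-01
131,2.965823387e-01
132,2.955369352e-01
133,2.945090496e-01
134,2.934981310e-01
135,2.925036518e-01
136,2.915251061e-01
137,2.905620091e-01
138,2.896138956e-01
139,2.886803196e-01
140,2.877608526e-01
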