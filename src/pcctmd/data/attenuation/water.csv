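energy_keV,mu_per_cm
1,4.390468597e+03
2,5.505439115e+02
3,1.637355487e+02
4,6.939496731e+01
5,3.573495954e+01
6,2.082815467e+01
7,1.323189320e+01
8,8.959087713e+00
9,6.372583807e+00
10,4.715395875e+00
11,3.604475963e+00
12,2.831736083e+00
13,2.277455062e+00
14,1.869407436e+00
15,1.562249046e+00
16,1.326527938e+00
17,1.142544953e+00
18,9.967827164e-01
19,8.797545595e-01
20,7.846683489e-01
21,7.065736664e-01
22,6.418041504e-01
23,5.876048415e-01
24,5.418782336e-01
25,5.030081166e-01
26,4.697353882e-01
27,4.410691989e-01
28,4.162225058e-01
29,3.945647417e-01
30,3.755866494e-01
31,3.588738709e-01
32,3.440869136e-01
33,3.309458119e-01
34,3.192182796e-01
35,3.087104851e-01
36,2.992598124e-01
37,2.907291406e-01
38,2.830022911e-01
39,2.759803822e-01
40,2.695788917e-01
41,2.637252767e-01
42,2.583570340e-01
43,2.534201124e-01
44,2.488676050e-01
45,2.446586687e-01
46,2.407576262e-01
47,2.371332175e-01
48,2.337579727e-01
49,2.306076846e-01
50,2.276609639e-01
51,2.248988623e-01
52,2.223045524e-01
53,2.198630545e-01
54,2.175610031e-01
55,2.153864468e-01
56,2.133286757e-01
57,2.113780726e-01
58,2.095259845e-01
59,2.077646112e-01
60,2.060869077e-01
61,2.044865001e-01
62,2.029576115e-01
63,2.014949972e-01
64,2.000938878e-01
65,1.987499397e-01
66,1.974591905e-01
67,1.962180204e-01
68,1.950231178e-01
69,1.938714485e-01
70,1.927602291e-01
71,1.916869024e-01
72,1.906491164e-01
73,1.896447046e-01
74,1.886716693e-01
75,1.877281661e-01
76,1.868124901e-01
77,1.859230634e-01
78,1.850584244e-01
79,1.842172173e-01
80,1.833981833e-01
81,1.826001525e-01
82,1.818220363e-01
83,1.810628210e-01
84,1.803215614e-01
85,1.795973756e-01
86,1.788894398e-01
87,1.781969839e-01
88,1.775192872e-01
89,1.768556747e-01
90,1.762055137e-01
91,1.755682105e-01
92,1.749432077e-01
93,1.743299815e-01
94,1.737280391e-01
95,1.731369167e-01
96,1.725561773e-01
97,1.719854091e-01
98,1.714242233e-01
99,1.708722530e-01
100,1.703291514e-01
101,1.697945906e-01
102,1.692682604e-01
103,1.687498669e-01
104,1.682391317e-01
105,1.677357908e-01
106,1.672395938e-01
107,1.667503027e-01
108,1.662676915e-01
109,1.657915454e-01
110,1.653216600e-01
111,1.648578407e-01
112,1.643999022e-01
113,1.639476677e-01
114,1.635009688e-01
115,1.630596447e-01
116,1.626235419e-01
117,1.621925138e-01
118,1.617664202e-01
119,1.613451269e-01
120,1.609285058e-01
121,1.605164338e-01
122,1.601087934e-01
123,1.597054718e-01
124,1.593063606e-01
125,1.589113562e-01
126,1.585203588e-01
127,1.581332727e-01
128,1.577500059e-01
129,1.573704701e-01
130,1.569945801e-01
131,1.566222540e-01
132,1.562534131e-01
133,1.558879814e-01
134,1.555258857e-01
135,1.551670554e-01
136,1.548114226e-01
137,1.544589215e-01
138,1.541094887e-01
139,1.537630631e-01
140,1.534195854e-01
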