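energy_keV,mu_per_cm
1,4.579786747e+03
2,5.742598466e+02
3,1.707825306e+02
4,7.237943020e+01
5,3.727097747e+01
6,2.172315848e+01
7,1.380047313e+01
8,9.344183737e+00
9,6.646684394e+00
10,4.918428188e+00
11,3.759897590e+00
12,2.954061429e+00
13,2.376055336e+00
14,1.950552360e+00
15,1.630262000e+00
16,1.384468642e+00
17,1.192628266e+00
18,1.040644009e+00
19,9.186226715e-01
20,8.194811816e-01
21,7.380571578e-01
22,6.705273196e-01
23,6.140188446e-01
24,5.663445276e-01
25,5.258190696e-01
26,4.911295673e-01
27,4.612428490e-01
28,4.353382687e-01
29,4.127583478e-01
30,3.929721034e-01
31,3.755475073e-01
32,3.601305955e-01
33,3.464294727e-01
34,3.342019589e-01
35,3.232459695e-01
36,3.133919676e-01
37,3.044969985e-01
38,2.964399428e-01
39,2.891177151e-01
40,2.824422015e-01
41,2.763377774e-01
42,2.707392855e-01
43,2.655903802e-01
44,2.608421643e-01
45,2.564520621e-01
46,2.523828837e-01
47,2.486020439e-01
48,2.450809088e-01
49,2.417942459e-01
50,2.387197603e-01
51,2.358377015e-01
52,2.331305300e-01
53,2.305826326e-01
54,2.281800785e-01
55,2.259104111e-01
56,2.237624677e-01
57,2.217262249e-01
58,2.197926643e-01
59,2.179536561e-01
60,2.162018582e-01
61,2.145306274e-01
62,2.129339432e-01
63,2.114063397e-01
64,2.099428464e-01
65,2.085389364e-01
66,2.071904803e-01
67,2.058937059e-01
68,2.046451618e-01
69,2.034416863e-01
70,2.022803785e-01
71,2.011585737e-01
72,2.000738206e-01
73,1.990238617e-01
74,1.980066152e-01
75,1.970201589e-01
76,1.960627163e-01
77,1.951326430e-01
78,1.942284159e-01
79,1.933486222e-01
80,1.924919502e-01
81,1.916571805e-01
82,1.908431790e-01
83,1.900488891e-01
84,1.892733260e-01
85,1.885155706e-01
86,1.877747645e-01
87,1.870501050e-01
88,1.863408413e-01
89,1.856462698e-01
90,1.849657313e-01
91,1.842986070e-01
92,1.836443161e-01
93,1.830023126e-01
94,1.823720831e-01
95,1.817531441e-01
96,1.811450404e-01
97,1.805473425e-01
98,1.799596455e-01
99,1.793815669e-01
100,1.788127452e-01
101,1.782528388e-01
102,1.777015242e-01
103,1.771584953e-01
104,1.766234618e-01
105,1.760961486e-01
106,1.755762945e-01
107,1.750636517e-01
108,1.745579846e-01
109,1.740590691e-01
110,1.735666922e-01
111,1.730806511e-01
112,1.726007526e-01
113,1.721268124e-01
114,1.716586550e-01
115,1.711961126e-01
116,1.707390254e-01
117,1.702872404e-01
118,1.698406114e-01
119,1.693989986e-01
120,1.689622682e-01
121,1.685302922e-01
122,1.681029478e-01
123,1.676801173e-01
124,1.672616880e-01
125,1.668475516e-01
126,1.664376040e-01
127,1.660317456e-01
128,1.656298804e-01
129,1.652319160e-01
130,1.648377639e-01
131,1.644473385e-01
132,1.640605577e-01
133,1.636773423e-01
134,1.632976158e-01
135,1.629213048e-01
136,1.625483381e-01
137,1.621786474e-01
138,1.618121664e-01
139,1.614488313e-01
140,1.610885802e-01
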