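genotype_id,normal_depth,normal_density,stress_depth,stress_density
1,deep,semi_dense,semi_deep,semi_dense
2,semi_deep,semi_dense,deep,semi_dense
3,semi_deep,dense,superficial,non_dense
4,deep,semi_dense,superficial,non_dense
5,semi_deep,semi_dense,superficial,semi_dense
6,semi_deep,semi_dense,superficial,semi_dense
7,semi_deep,non_dense,superficial,semi_dense
8,semi_deep,semi_dense,semi_deep,semi_dense
9,superficial,semi_dense,superficial,non_dense
10,superficial,semi_dense,superficial,semi_dense
11,deep,non_dense,superficial,non_dense
12,superficial,semi_dense,superficial,non_dense
13,superficial,non_dense,superficial,semi_dense
14,deep,semi_dense,semi_deep,semi_dense
15,semi_deep,non_dense,superficial,semi_dense
16,semi_deep,semi_dense,semi_deep,semi_dense
17,semi_deep,semi_dense,semi_deep,semi_dense
18,superficial,semi_dense,semi_deep,semi_dense
19,semi_deep,dense,semi_deep,semi_dense
20,semi_deep,non_dense,semi_deep,dense
21,superficial,non_dense,superficial,non_dense
22,deep,semi_dense,semi_deep,non_dense
23,semi_deep,semi_dense,superficial,semi_dense
24,deep,semi_dense,semi_deep,non_dense
25,semi_deep,semi_dense,semi_deep,non_dense
26,superficial,dense,semi_deep,non_dense
27,superficial,dense,semi_deep,non_dense
28,semi_deep,dense,semi_deep,non_dense
29,superficial,dense,semi_deep,semi_dense
30,semi_deep,dense,semi_deep,semi_dense
31,semi_deep,non_dense,semi_deep,semi_dense
32,superficial,non_dense,semi_deep,semi_dense
33,semi_deep,non_dense,deep,semi_dense
34,semi_deep,non_dense,deep,semi_dense
35,deep,semi_dense,semi_deep,semi_dense
36,semi_deep,non_dense,semi_deep,semi_dense
37,superficial,non_dense,superficial,semi_dense
38,superficial,non_dense,superficial,dense
39,semi_deep,non_dense,semi_deep,semi_dense
40,semi_deep,non_dense,semi_deep,semi_dense
41,semi_deep,non_dense,semi_deep,semi_dense
42,semi_deep,non_dense,semi_deep,non_dense
43,semi_deep,non_dense,semi_deep,semi_dense
44,deep,non_dense,deep,semi_dense
45,semi_deep,non_dense,deep,semi_dense
46,semi_deep,non_dense,semi_deep,semi_dense
47,semi_deep,non_dense,semi_deep,semi_dense
48,deep,non_dense,semi_deep,semi_dense
49,superficial,non_dense,semi_deep,non_dense
50,semi_deep,non_dense,superficial,non_dense
51,superficial,non_dense,superficial,semi_dense
52,semi_deep,semi_dense,semi_deep,semi_dense
53,superficial,non_dense,superficial,non_dense
54,semi_deep,semi_dense,semi_deep,semi_dense
55,semi_deep,semi_dense,semi_deep,semi_dense
56,semi_deep,non_dense,semi_deep,non_dense
57,semi_deep,dense,semi_deep,semi_dense
58,semi_deep,non_dense,semi_deep,semi_dense
59,semi_deep,semi_dense,semi_deep,semi_dense
60,semi_deep,dense,semi_deep,semi_dense
61,deep,semi_dense,semi_deep,semi_dense
62,semi_deep,semi_dense,superficial,semi_dense
63,semi_deep,semi_dense,semi_deep,dense
64,superficial,non_dense,superficial,semi_dense
65,semi_deep,non_dense,semi_deep,semi_dense
66,semi_deep,non_dense,deep,semi_dense
67,deep,semi_dense,semi_deep,dense
68,semi_deep,semi_dense,semi_deep,dense
69,semi_deep,semi_dense,semi_deep,non_dense
70,deep,semi_dense,deep,non_dense
71,semi_deep,dense,semi_deep,non_dense
72,semi_deep,semi_dense,semi_deep,non_dense
73,semi_deep,non_dense,semi_deep,dense
74,semi_deep,semi_dense,semi_deep,non_dense
75,semi_deep,dense,deep,semi_dense
76,semi_deep,semi_dense,semi_deep,semi_dense
77,semi_deep,semi_dense,semi_deep,dense
78,semi_deep,semi_dense,semi_deep,semi_dense
79,superficial,non_dense,semi_deep,semi_dense
80,semi_deep,semi_dense,deep,semi_dense
81,deep,non_dense,deep,non_dense
82,deep,semi_dense,deep,semi_dense
83,deep,non_dense,semi_deep,dense
84,deep,semi_dense,semi_deep,semi_dense
85,semi_deep,semi_dense,deep,non_dense
86,deep,dense,deep,non_dense
87,deep,dense,deep,semi_dense
88,semi_deep,semi_dense,semi_deep,non_dense
89,semi_deep,non_dense,semi_deep,non_dense
90,semi_deep,non_dense,superficial,non_dense
91,superficial,semi_dense,superficial,semi_dense
92,deep,non_dense,deep,semi_dense
93,deep,semi_dense,semi_deep,semi_dense
94,semi_deep,semi_dense,semi_deep,dense
95,semi_deep,semi_dense,deep,semi_dense
96,deep,semi_dense,deep,non_dense
97,deep,semi_dense,semi_deep,semi_dense
98,deep,dense,deep,semi_dense
99,deep,dense,semi_deep,non_dense
100,deep,semi_dense,superficial,dense
101,deep,semi_dense,semi_deep,dense
102,deep,semi_dense,semi_deep,dense
103,deep,semi_dense,superficial,semi_dense
104,semi_deep,dense,superficial,dense
105,superficial,dense,superficial,semi_dense
106,deep,semi_dense,deep,semi_dense
107,semi_deep,semi_dense,deep,dense
108,deep,non_dense,deep,semi_dense
109,semi_deep,non_dense,semi_deep,non_dense
110,semi_deep,dense,semi_deep,semi_dense
111,deep,dense,deep,dense
112,deep,semi_dense,deep,semi_dense
113,semi_deep,non_dense,semi_deep,semi_dense
114,semi_deep,semi_dense,deep,dense
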