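sample_id	x	y
0	0.0	0.0
1	-2.0	0.0
2	-1.0	-1.732051
3	-1.0	1.732051
4	1.0	-1.732051
5	1.0	1.732051
6	2.0	0.0
7	-3.0	-1.732051
8	-3.0	1.732051
9	0.0	-3.464102
10	0.0	3.464102
11	3.0	-1.732051
12	3.0	1.732051
13	-4.0	0.0
14	-2.0	-3.464102
15	-2.0	3.464102
16	2.0	-3.464102
17	2.0	3.464102
18	4.0	0.0
19	-5.0	-1.732051
20	-5.0	1.732051
21	-4.0	-3.464102
22	-4.0	3.464102
23	-1.0	-5.196152
24	-1.0	5.196152
25	1.0	-5.196152
26	1.0	5.196152
27	4.0	-3.464102
28	4.0	3.464102
29	5.0	-1.732051
30	5.0	1.732051
31	-6.0	0.0
32	-3.0	-5.196152
33	-3.0	5.196152
34	3.0	-5.196152
35	3.0	5.196152
36	6.0	0.0
37	-6.0	-3.464102
38	-6.0	3.464102
39	0.0	-6.928203
40	0.0	6.928203
41	6.0	-3.464102
42	6.0	3.464102
43	-7.0	-1.732051
44	-7.0	1.732051
45	-5.0	-5.196152
46	-5.0	5.196152
47	-2.0	-6.928203
48	-2.0	6.928203
49	2.0	-6.928203
50	2.0	6.928203
51	5.0	-5.196152
52	5.0	5.196152
53	7.0	-1.732051
54	7.0	1.732051
55	-8.0	0.0
56	-4.0	-6.928203
57	-4.0	6.928203
58	4.0	-6.928203
59	4.0	6.928203
60	8.0	0.0
61	-8.0	-3.464102
62	-8.0	3.464102
63	-7.0	-5.196152
64	-7.0	5.196152
65	-1.0	-8.660254
66	-1.0	8.660254
67	1.0	-8.660254
68	1.0	8.660254
69	7.0	-5.196152
70	7.0	5.196152
71	8.0	-3.464102
72	8.0	3.464102
73	-9.0	-1.732051
74	-9.0	1.732051
75	-6.0	-6.928203
76	-6.0	6.928203
77	-3.0	-8.660254
78	-3.0	8.660254
79	3.0	-8.660254
80	3.0	8.660254
81	6.0	-6.928203
82	6.0	6.928203
83	9.0	-1.732051
84	9.0	1.732051
85	-10.0	0.0
86	-5.0	-8.660254
87	-5.0	8.660254
88	5.0	-8.660254
89	5.0	8.660254
90	10.0	0.0
91	-9.0	-5.196152
92	-9.0	5.196152
93	0.0	-10.392305
94	0.0	10.392305
95	9.0	-5.196152
96	9.0	5.196152
97	-10.0	-3.464102
98	-10.0	3.464102
99	-8.0	-6.928203
100	-8.0	6.928203
101	-2.0	-10.392305
102	-2.0	10.392305
103	2.0	-10.392305
104	2.0	10.392305
105	8.0	-6.928203
106	8.0	6.928203
107	10.0	-3.464102
108	10.0	3.464102
109	-11.0	-1.732051
110	-11.0	1.732051
111	-7.0	-8.660254
112	-7.0	8.660254
113	-4.0	-10.392305
114	-4.0	10.392305
115	4.0	-10.392305
116	4.0	10.392305
117	7.0	-8.660254
118	7.0	8.660254
119	11.0	-1.732051
120	11.0	1.732051
121	-12.0	0.0
122	-6.0	-10.392305
123	-6.0	10.392305
124	6.0	-10.392305
125	6.0	10.392305
126	12.0	0.0
127	-11.0	-5.196152
128	-11.0	5.196152
129	-10.0	-6.928203
130	-10.0	6.928203
131	-1.0	-12.124356
132	-1.0	12.124356
133	1.0	-12.124356
134	1.0	12.124356
135	10.0	-6.928203
136	10.0	6.928203
137	11.0	-5.196152
138	11.0	5.196152
139	-12.0	-3.464102
140	-12.0	3.464102
141	-9.0	-8.660254
142	-9.0	8.660254
143	-3.0	-12.124356
144	-3.0	12.124356
145	3.0	-12.124356
146	3.0	12.124356
147	9.0	-8.660254
148	9.0	8.660254
149	12.0	-3.464102
150	12.0	3.464102
151	-13.0	-1.732051
152	-13.0	1.732051
153	-8.0	-10.392305
154	-8.0	10.392305
155	-5.0	-12.124356
156	-5.0	12.124356
157	5.0	-12.124356
158	5.0	12.124356
159	8.0	-10.392305
160	8.0	10.392305
161	13.0	-1.732051
162	13.0	1.732051
163	-12.0	-6.928203
164	-12.0	6.928203
165	0.0	-13.856406
166	0.0	13.856406
167	12.0	-6.928203
168	12.0	6.928203
169	-14.0	0.0
170	-13.0	-5.196152
171	-13.0	5.196152
172	-11.0	-8.660254
173	-11.0	8.660254
174	-7.0	-12.124356
175	-7.0	12.124356
176	-2.0	-13.856406
177	-2.0	13.856406
178	2.0	-13.856406
179	2.0	13.856406
180	7.0	-12.124356
181	7.0	12.124356
182	11.0	-8.660254
183	11.0	8.660254
184	13.0	-5.196152
185	13.0	5.196152
186	14.0	0.0
187	-14.0	-3.464102
188	-14.0	3.464102
189	-10.0	-10.392305
190	-10.0	10.392305
191	-4.0	-13.856406
192	-4.0	13.856406
193	4.0	-13.856406
194	4.0	13.856406
195	10.0	-10.392305
196	10.0	10.392305
197	14.0	-3.464102
198	14.0	3.464102
199	-15.0	-1.732051
200	-15.0	1.732051
201	-9.0	-12.124356
202	-9.0	12.124356
203	-6.0	-13.856406
204	-6.0	13.856406
205	6.0	-13.856406
206	6.0	13.856406
207	9.0	-12.124356
208	9.0	12.124356
209	15.0	-1.732051
210	15.0	1.732051
211	-14.0	-6.928203
212	-14.0	6.928203
213	-13.0	-8.660254
214	-13.0	8.660254
215	-1.0	-15.588457
216	-1.0	15.588457
217	1.0	-15.588457
218	1.0	15.588457
219	13.0	-8.660254
220	13.0	8.660254
221	14.0	-6.928203
222	14.0	6.928203
223	-15.0	-5.196152
224	-15.0	5.196152
225	-12.0	-10.392305
226	-12.0	10.392305
227	-3.0	-15.588457
228	-3.0	15.588457
229	3.0	-15.588457
230	3.0	15.588457
231	12.0	-10.392305
232	12.0	10.392305
233	15.0	-5.196152
234	15.0	5.196152
235	-16.0	0.0
236	-8.0	-13.856406
237	-8.0	13.856406
238	8.0	-13.856406
239	8.0	13.856406
240	16.0	0.0
241	-16.0	-3.464102
242	-16.0	3.464102
243	-11.0	-12.124356
244	-11.0	12.124356
245	-5.0	-15.588457
246	-5.0	15.588457
247	5.0	-15.588457
248	5.0	15.588457
249	11.0	-12.124356
250	11.0	12.124356
251	16.0	-3.464102
252	16.0	3.464102
253	-17.0	-1.732051
254	-17.0	1.732051
255	-10.0	-13.856406
256	-10.0	13.856406
257	-7.0	-15.588457
258	-7.0	15.588457
259	7.0	-15.588457
260	7.0	15.588457
261	10.0	-13.856406
262	10.0	13.856406
263	17.0	-1.732051
264	17.0	1.732051
265	-15.0	-8.660254
266	-15.0	8.660254
267	0.0	-17.320508
268	0.0	17.320508
269	15.0	-8.660254
270	15.0	8.660254
271	-16.0	-6.928203
272	-16.0	6.928203
273	-14.0	-10.392305
274	-14.0	10.392305
275	-2.0	-17.320508
276	-2.0	17.320508
277	2.0	-17.320508
278	2.0	17.320508
279	14.0	-10.392305
280	14.0	10.392305
281	16.0	-6.928203
282	16.0	6.928203
283	-17.0	-5.196152
284	-17.0	5.196152
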