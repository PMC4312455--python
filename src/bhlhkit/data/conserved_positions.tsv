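column	region	allowed_residues	frequencies
1	basic	K,R,N	K:28,R:25,N:11
2	basic	R,K	R:32,K:11
13	basic	E,A	E:75,A:11
14	basic	R,K	R:76,K:18
16	basic	R	R:94
20	helix1	I,L,M	I:53,L:28,M:17
21	helix1	N,S	N:45,S:26
24	helix1	L,F,M,I	L:28,F:26,M:19,I:16
27	helix1	L	L:99
28	helix1	Q,R	Q:41,R:37
36	loop	K	K:68
47	helix2	K,T	K:45,T:21
50	helix2	M,I,V,L	M:33,I:28,V:15,L:14
51	helix2	L,I	L:78,I:11
54	helix2	A,I,V,T	A:60,I:18,V:11,T:10
55	helix2	I,V	I:60,V:25
57	helix2	Y,H	Y:74,H:13
58	helix2	I,V,L	I:43,V:38,L:13
61	helix2	L	L:97
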