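matched_refs	extra_introns	label
1,2,3	0	I
1,2	0	II
1,3	0	III
2,3	0	IV
1	0	V
2	0	VI
3	0	VII
1	1	VIII
-	1	IX
-	2	X
-	0	XI
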