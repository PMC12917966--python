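sample	10348	14321	23167	23593	29449	37238	37239	37240	45193	45592	50158	50842	50999	59616	65304	68985	90253	95372	97585	98314	101103	101121	101130	101139	101148	101157	106236	110347	113045	118329	119153	119714
REF	T	G	G	C	T	T	T	T	G	G	T	C	G	C	C	G	A	G	T	G	T	T	T	G	G	T	G	T	T	C	G	C
ALT	A	T	A	A	G	A	A	A	T	T	C	T	A	T	A	T	G	A	G	T	G	G	G	T	T	G	A	G	G	A	T	T
Ⅰ-22	-	T	-	-	-	A	A	A	T	-	-	-	-	-	-	T	G	-	-	-	-	-	G	T	T	-	-	-	G	A	-	-
Ⅰ-54	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	G	G	-	-	-	-	-	-	-	T	-
Ⅰ-56	-	-	A	A	-	-	-	-	T	-	-	T	A	-	-	T	-	-	-	-	G	G	-	T	-	-	-	-	-	N	-	N
Ⅰ-58	-	-	-	A	-	-	-	-	T	-	-	T	N	-	-	T	-	-	-	-	G	-	-	T	-	-	-	-	-	-	N	-
Ⅱ-12	-	-	-	N	-	-	-	-	T	-	-	-	-	-	-	T	G	-	-	-	-	-	-	-	-	-	-	N	-	-	N	-
Ⅱ-16-4	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	-	-	-	-	-	-	-	T	T
Ⅱ-16-5	-	-	A	A	-	A	A	A	T	-	-	T	A	-	-	T	-	-	-	-	G	G	-	-	-	-	-	-	-	-	-	-
Ⅱ-19	A	-	-	-	-	-	-	-	T	-	-	-	-	T	-	T	-	-	-	-	-	-	-	-	-	G	-	-	-	-	T	-
Ⅱ-31-5	-	-	-	A	-	A	A	A	T	-	C	T	A	-	-	T	-	-	-	-	G	-	-	T	-	-	A	-	-	-	-	-
Ⅱ-31-6	-	-	-	-	-	A	A	A	T	-	-	-	-	-	-	T	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Ⅱ-4-1	-	-	-	-	-	-	-	-	T	T	-	-	-	-	-	T	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Ⅱ-4-5	-	-	-	-	-	-	-	-	T	T	-	-	-	-	-	T	-	-	-	-	-	-	-	-	-	-	-	-	-	N	T	-
Ⅱ-4-6	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	G	-	-	-	-	-	-	-	-	-	-	-	-	-	T	-
Ⅱ-51-6	A	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	T	G	-	-	T	-	-	-	-	-	-	N	-
Ⅱ-55-2	-	-	-	-	N	N	N	N	T	-	-	-	-	-	-	T	G	-	-	-	-	G	-	T	-	-	-	-	-	N	-	-
Ⅱ-57-2	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	-	-	-	G	-	-	-	-	-	-
Ⅱ-57-5	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	-	T	T	-	-	-	-	-	-	T
Ⅱ-6-2	-	T	-	-	-	A	A	A	T	-	-	-	-	-	-	T	-	-	-	-	-	-	G	T	T	-	-	-	G	A	-	-
Ⅱ-6-6	-	-	A	A	-	-	-	-	T	-	-	T	A	-	-	T	-	-	-	-	G	G	-	T	T	-	-	-	N	-	-	-
Ⅲ-11	-	-	-	-	-	-	-	-	T	-	-	-	-	-	A	T	-	A	G	-	-	-	-	T	-	-	-	-	-	-	-	-
Ⅲ-16-1	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	G	G	-	-	-	-	G	-	-	-	-
Ⅲ-16-4	-	-	N	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	N	G	G	-	-	-	-	G	N	N	-	-
Ⅲ-16-6	-	-	-	N	-	-	-	-	T	-	-	-	-	-	-	T	G	-	-	-	-	G	G	-	-	-	-	-	-	-	T	-
Ⅲ-19	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	-	-	-	-	-	-	-	T	-
Ⅲ-20	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	-	T	-	-	-	-	-	T	-
Ⅲ-4-1	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Ⅲ-4-4	-	-	-	-	-	-	-	-	T	T	-	-	-	-	-	T	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-
Ⅲ-5	-	-	-	-	N	N	N	N	T	-	-	N	N	-	-	N	G	-	-	-	G	-	-	-	-	-	T	N	-	N	N	N
Ⅲ-51-3	-	-	-	-	-	-	-	-	T	-	-	-	-	-	A	T	-	A	G	-	-	-	-	T	-	-	-	-	-	-	T	-
Ⅲ-54-2	-	-	-	A	-	A	A	A	T	-	C	T	A	-	-	T	-	-	-	-	G	-	-	T	-	-	A	-	-	-	-	-
Ⅲ-55	-	-	-	A	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	G	T	-	-	-	-	-	-	-	-
Ⅲ-56-1	-	-	-	-	-	N	N	N	T	-	-	-	-	-	-	T	-	-	-	T	G	-	G	-	-	-	-	-	-	-	T	-
Ⅲ-64	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	-	T	T	-	-	-	-	-	-	-
Ⅳ-11-3	N	-	-	A	-	A	A	A	T	-	C	T	A	-	-	T	-	-	-	-	G	-	-	T	-	-	A	-	-	-	-	-
Ⅳ-11-5	-	-	-	-	G	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	G	-	-	-	-	-	G	-	N	-
Ⅳ-16	-	-	-	A	-	A	A	A	T	-	C	T	A	-	-	T	G	-	-	-	G	-	-	T	-	-	A	-	-	N	-	-
Ⅳ-17-1	-	-	-	-	-	-	-	-	N	N	-	-	-	T	-	T	-	-	N	-	-	-	-	-	-	G	-	-	-	N	N	-
Ⅳ-17-4	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	-	-	-	-	-	-	-	T	-
Ⅳ-19	A	-	-	-	-	-	-	-	T	-	-	-	-	T	-	T	-	-	-	-	-	-	-	-	-	G	-	-	-	-	N	A
Ⅳ-19-4	-	-	-	-	-	-	-	-	T	-	-	-	-	-	A	T	-	A	G	-	-	-	-	T	-	-	-	-	-	-	-	-
Ⅳ-40-2	-	-	-	-	-	-	-	-	T	-	-	T	A	-	-	T	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Ⅳ-40-5	N	-	-	-	-	-	-	-	T	-	-	T	A	-	-	T	-	-	-	-	-	-	G	T	-	-	-	-	-	-	-	-
Ⅳ-55	-	-	-	-	G	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	G	-	-	-	-	-	G	-	-	-
Ⅳ-57	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	G	G	-	-	-	-	G	-	-	-	-
Ⅳ-58-4	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	T	-	-	-	-	-	-	-	-
Ⅴ-1	-	T	-	-	-	A	A	A	T	-	-	-	-	-	-	T	-	-	-	-	-	-	G	T	T	-	-	-	G	A	-	-
Ⅴ-14	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	-	T	-	-	-	-	-	T	-
Ⅵ-11	-	-	-	-	-	-	A	A	T	-	-	N	-	-	-	T	-	-	-	T	-	-	-	T	-	G	-	-	-	N	T	-
Ⅵ-12	N	-	-	-	-	N	N	N	T	-	-	-	-	-	-	T	-	-	-	-	N	N	N	N	-	-	-	-	-	-	N	N
Ⅵ-14	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	-	-	-	-	-	-	-	-	T	T
Ⅵ-16	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	G	G	-	-	-	-	G	-	-	-	-
Ⅵ-19	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	-	-	-	T	-	G	-	-	-	N	N	N
Ⅵ-58	-	-	-	-	-	-	-	-	T	-	-	-	-	-	-	T	-	-	-	T	G	-	-	T	-	-	-	-	-	N	T	-
Ⅵ-58-6	-	-	-	-	G	-	-	-	T	-	-	-	-	-	-	T	-	-	-	-	G	-	G	-	-	-	-	-	G	-	-	T
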