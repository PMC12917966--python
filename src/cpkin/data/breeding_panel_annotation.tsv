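position	ref	alt	label	products
10348	T	A	trnG-GCC	tRNA-Gly
14321	G	T	atpH	ATP synthase CF0 C subunit
23167	G	A	rpoC1	RNA polymerase beta' subunit
23593	C	A	rpoC1 ~ rpoB	RNA polymerase beta' subunit, RNA polymerase beta subunit
29449	T	G	psbM ~ trnD-GCA	photosystem II protein M, tRNA-Asp
37238	T	A	psbJ ~ petA	photosystem II protein J, cytochrome f
37239	T	A	psbJ ~ petA	photosystem II protein J, cytochrome f
37240	T	A	psbJ ~ petA	photosystem II protein J, cytochrome f
45193	G	T	rbcL ~ atpB	ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit, ATP synthase CF1 beta subunit
45592	G	T	rbcL ~ atpB	ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit, ATP synthase CF1 beta subunit
50158	T	C	trnV-UAC ~ trnH-GUG	tRNA-Val, tRNA-His
50842	C	T	trnH-GUG ~ trnT-GGU	tRNA-His, tRNA-Thr
50999	G	A	trnT-GGU ~ rps4	tRNA-Thr, pseudo
59616	C	T	rps11	ribosomal protein S11
65304	C	A	rpl2	ribosomal protein L2
68985	G	T	trnL-UAA ~ trnT-UGU	tRNA-Leu, tRNA-Thr
90253	A	G	rrn23	23S ribosomal RNA
95372	G	A	chlN	photochlorophyllide reductase subunit N
97585	T	G	ycf1	hypothetical chloroplast protein
98314	G	T	ycf1	hypothetical chloroplast protein
101103	T	G	ycf1	hypothetical chloroplast protein
101121	T	G	ycf1	hypothetical chloroplast protein
101130	T	G	ycf1	hypothetical chloroplast protein
101139	G	T	ycf1	hypothetical chloroplast protein
101148	G	T	ycf1	hypothetical chloroplast protein
101157	T	G	ycf1	hypothetical chloroplast protein
106236	G	A	psaC ~ ccsA	photosystem I subunit VII, cytochrome c biogenesis protein
110347	T	G	trnV-GAC ~ rps7	tRNA-Val, ribosomal protein S7
113045	T	G	rps7 ~ trnL-CAA	ribosomal protein S7, tRNA-Leu
118329	C	A	ycf2	hypothetical chloroplast protein
119153	G	T	ycf2	hypothetical chloroplast protein
119714	C	T	ycf2	hypothetical chloroplast protein
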