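name	start	end	strand	product
trnG-GCC	10300	10390	+	tRNA-Gly
atpH	14250	14500	-	ATP synthase CF0 C subunit
rpoC1	21000	23500	-	RNA polymerase beta' subunit
rpoB	24000	27200	-	RNA polymerase beta subunit
psbM	29100	29300	-	photosystem II protein M
trnD-GCA	29600	29680	-	tRNA-Asp
psbJ	36800	36950	-	photosystem II protein J
petA	37800	38760	+	cytochrome f
rbcL	43500	44930	+	ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit
atpB	45800	47290	-	ATP synthase CF1 beta subunit
trnV-UAC	50050	50130	-	tRNA-Val
trnH-GUG	50700	50780	+	tRNA-His
trnT-GGU	50900	50970	+	tRNA-Thr
rps4	51200	51800	-	pseudo
rps11	59500	59920	-	ribosomal protein S11
rpl2	65100	66600	-	ribosomal protein L2
trnL-UAA	68700	68790	+	tRNA-Leu
trnT-UGU	69200	69270	-	tRNA-Thr
rrn23	88900	91700	+	23S ribosomal RNA
chlN	94900	96330	-	photochlorophyllide reductase subunit N
ycf1	97400	101300	+	hypothetical chloroplast protein
psaC	105900	106150	-	photosystem I subunit VII
ccsA	106800	107760	+	cytochrome c biogenesis protein
trnV-GAC	110200	110270	+	tRNA-Val
rps7	112500	112970	-	ribosomal protein S7
trnL-CAA	113400	113480	-	tRNA-Leu
ycf2	117300	120200	-	hypothetical chloroplast protein
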