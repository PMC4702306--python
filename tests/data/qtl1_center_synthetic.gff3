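##gff-version 3
# synthetic mini-annotation of the chrXIII QTL1 neighbourhood (gene
# coordinates invented for testing; not an SGD release)
##sequence-region chrXIII 1 924431
chrXIII	synthetic	gene	200100	201600	.	+	.	ID=YML010W;gene=FARFLANK1
chrXIII	synthetic	gene	248000	249800	.	-	.	ID=YML008C;gene=EDGE1
chrXIII	synthetic	gene	255200	256900	.	-	.	ID=YML006C;gene=GIS4
chrXIII	synthetic	gene	257400	259000	.	+	.	ID=YML005W;gene=TRM12
chrXIII	synthetic	gene	259600	260900	.	-	.	ID=YML004C;gene=GLO1
chrXIII	synthetic	gene	261500	262700	.	-	.	ID=YML003W;gene=YML003W
chrXIII	synthetic	gene	263300	264800	.	+	.	ID=YML002W;gene=YML002W
chrXIII	synthetic	gene	265400	267200	.	-	.	ID=YML001W;gene=YPT7
chrXIII	synthetic	gene	271500	273400	.	+	.	ID=YMR001W;gene=EDGE2
chrXIII	synthetic	gene	300500	302200	.	+	.	ID=YMR010W;gene=FARFLANK2
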