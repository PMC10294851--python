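# id=MT712139_Muscidifurax_similadanacus
# length=15080
# circular=true
gene	start	end	strand	type	start_codon	stop_codon
trnI	1	69	+	tRNA		
nad2	89	1096	-	PCG	ATT	TAA
trnW	1095	1161	-	tRNA		
trnY	1160	1226	+	tRNA		
trnS1	1233	1295	+	tRNA		
trnN	1299	1366	-	tRNA		
trnR	1362	1430	+	tRNA		
trnC	1433	1496	+	tRNA		
nad3	1500	1850	+	PCG	ATT	TAA
trnG	1851	1916	+	tRNA		
cox3	1917	2702	+	PCG	ATG	TAA
atp6	2702	3376	+	PCG	ATG	TAA
atp8	3367	3528	+	PCG	ATT	TAA
trnD	3529	3597	+	tRNA		
trnK	3601	3669	-	tRNA		
cox2	3670	4344	+	PCG	ATT	TAA
trnL2	4345	4410	+	tRNA		
cox1	4413	5942	+	PCG	ATG	TAA
trnE	5945	6010	-	tRNA		
trnF	6009	6072	+	tRNA		
nad5	6073	7741	+	PCG	ATT	T-
trnH	7750	7818	+	tRNA		
nad4	7819	9159	+	PCG	ATG	TAA
nad4l	9153	9440	+	PCG	ATT	TAA
trnT	9441	9504	-	tRNA		
trnP	9507	9575	+	tRNA		
nad6	9581	10126	-	PCG	ATG	TAA
cytb	10126	11271	-	PCG	ATG	TAA
trnS2	11271	11339	-	tRNA		
trnQ	11341	11408	+	tRNA		
nad1	11409	12338	+	PCG	ATT	TAA
trnL1	12339	12404	+	tRNA		
rrnL	12405	13717	+	rRNA		
trnA	13718	13782	+	tRNA		
rrnS	13783	14558	+	rRNA		
trnV	14559	14623	+	tRNA		
trnM	14626	14690	+	tRNA		
CR	14691	15080	+	control_region		
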