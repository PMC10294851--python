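# id=MT712140_Muscidifurax_sinesensilla
# length=15020
# circular=true
gene	start	end	strand	type	start_codon	stop_codon
trnI	1	68	+	tRNA		
nad2	87	1094	-	PCG	ATT	TAA
trnW	1101	1167	-	tRNA		
trnY	1166	1230	+	tRNA		
trnS1	1240	1302	+	tRNA		
trnN	1324	1391	-	tRNA		
trnR	1393	1463	+	tRNA		
trnC	1475	1537	+	tRNA		
nad3	1537	1887	+	PCG	ATT	TAA
trnG	1888	1954	+	tRNA		
cox3	1960	2745	+	PCG	ATG	TAA
atp6	2745	3419	+	PCG	ATG	TAA
atp8	3410	3571	+	PCG	ATT	TAA
trnD	3572	3636	+	tRNA		
trnK	3652	3722	-	tRNA		
cox2	3726	4400	+	PCG	ATT	TAA
trnL2	4401	4468	+	tRNA		
cox1	4471	6000	+	PCG	ATG	TAA
trnE	6003	6067	-	tRNA		
trnF	6072	6136	+	tRNA		
nad5	6137	7808	+	PCG	ATT	T-
trnH	7812	7877	+	tRNA		
nad4	7879	9219	+	PCG	ATG	TAA
nad4l	9213	9500	+	PCG	ATT	TAA
trnT	9501	9564	-	tRNA		
trnP	9565	9629	+	tRNA		
nad6	9633	10184	-	PCG	ATG	TAA
cytb	10185	11330	-	PCG	ATG	TAA
trnS2	11329	11396	-	tRNA		
trnQ	11409	11480	+	tRNA		
nad1	11484	12405	+	PCG	ATT	T-
trnL1	12406	12472	+	tRNA		
rrnL	12473	13780	+	rRNA		
trnA	13781	13845	+	tRNA		
rrnS	13846	14625	+	rRNA		
trnV	14626	14691	+	tRNA		
trnM	14694	14758	+	tRNA		
CR	14759	15020	+	control_region		
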