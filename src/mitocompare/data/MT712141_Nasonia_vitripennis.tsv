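# id=MT712141_Nasonia_vitripennis
# length=14791
# circular=true
gene	start	end	strand	type	start_codon	stop_codon
trnI	1	70	+	tRNA		
nad2	92	1102	-	PCG	ATA	TAA
trnW	1105	1171	-	tRNA		
trnY	1170	1237	+	tRNA		
trnS1	1240	1299	+	tRNA		
trnN	1302	1368	-	tRNA		
trnR	1375	1445	+	tRNA		
trnC	1448	1514	+	tRNA		
nad3	1514	1864	+	PCG	ATA	TAA
trnG	1865	1932	+	tRNA		
cox3	1935	2720	+	PCG	ATG	TAA
atp6	2723	3397	+	PCG	ATG	TAA
atp8	3391	3549	+	PCG	ATA	TAA
trnD	3551	3615	+	tRNA		
trnK	3619	3692	-	tRNA		
cox2	3696	4364	+	PCG	ATT	TAA
trnL2	4365	4432	+	tRNA		
cox1	4433	5963	+	PCG	ATG	T-
trnE	5964	6033	-	tRNA		
trnF	6045	6109	+	tRNA		
nad5	6109	7794	+	PCG	ATT	TAG
trnH	7795	7859	+	tRNA		
nad4	7860	9198	+	PCG	ATG	T-
nad4l	9192	9479	+	PCG	ATT	TAA
trnT	9479	9543	-	tRNA		
trnP	9544	9608	+	tRNA		
nad6	9617	10165	-	PCG	ATG	TAA
cytb	10167	11306	-	PCG	ATG	TAA
trnS2	11305	11371	-	tRNA		
trnQ	11398	11468	+	tRNA		
nad1	11469	12401	+	PCG	TTG	TAA
trnL1	12402	12468	+	tRNA		
rrnL	12469	13793	+	rRNA		
trnA	13794	13857	+	tRNA		
rrnS	13858	14644	+	rRNA		
trnV	14645	14712	+	tRNA		
trnM	14716	14787	+	tRNA		
CR	14788	14791	+	control_region		
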