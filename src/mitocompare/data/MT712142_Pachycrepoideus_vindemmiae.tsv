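# id=MT712142_Pachycrepoideus_vindemmiae
# length=14850
# circular=true
gene	start	end	strand	type	start_codon	stop_codon
trnR	1	59	-	tRNA		
trnI	63	131	+	tRNA		
nad2	167	1168	-	PCG	ATT	TAA
trnW	1172	1241	-	tRNA		
trnY	1240	1305	+	tRNA		
trnS1	1307	1366	+	tRNA		
trnN	1370	1438	+	tRNA		
trnC	1440	1504	+	tRNA		
nad3	1505	1853	+	PCG	ATT	T-
trnG	1854	1918	+	tRNA		
cox3	1919	2704	+	PCG	ATG	TAA
atp6	2704	3378	+	PCG	ATG	TAA
atp8	3372	3530	+	PCG	ATT	TAA
trnD	3544	3608	+	tRNA		
trnK	3618	3689	-	tRNA		
cox2	3691	4359	+	PCG	ATT	TAA
trnL2	4360	4425	+	tRNA		
cox1	4426	5959	+	PCG	ATG	T-
trnF	5958	6020	-	tRNA		
trnE	6021	6085	+	tRNA		
nad5	6086	7757	+	PCG	ATT	T-
trnH	7760	7823	+	tRNA		
nad4	7824	9156	+	PCG	ATG	T-
nad4l	9150	9437	+	PCG	ATT	TAA
trnT	9437	9506	-	tRNA		
trnP	9514	9577	+	tRNA		
nad6	9581	10147	-	PCG	ATG	TAA
cytb	10147	11283	-	PCG	ATG	TAA
trnS2	11282	11348	-	tRNA		
trnQ	11364	11418	+	tRNA		
nad1	11420	12340	+	PCG	ATT	TAA
trnL1	12341	12405	+	tRNA		
rrnL	12406	13705	+	rRNA		
trnA	13706	13770	+	tRNA		
rrnS	13771	14533	+	rRNA		
trnV	14534	14600	+	tRNA		
trnM	14601	14667	+	tRNA		
CR	14668	14850	+	control_region		
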