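record_id	table_kind	gene_symbols	aliases	cleft_type	penetrance_note	pmids	note
single-01	single	Bmp4		CLO	Nestin-Cre;Bmp4 F/n cKO mice show unilateral CL.	15716346	
single-02	single	Bmpr1a		CLP	Nestin-Cre;Bmpr1a cKO mice show bilateral CL and CP.	15716346	
single-03	single	Cdc42		CLP or CPO	Wnt1-Cre;Cdc42 cKO mice show either unilateral or bilateral CL at 10% and CP at 100%.	24056078	
single-04	single	Clpex		midfacial cleft and CLP	Homozygous mutant mice show several types of facial clefting (midfacial cleft and bilateral CL) and CP	21515572	
single-05	single	Cplane1		CLP	Homozygous mutant mice show CL and CP.	25877302	
single-06	single	Cplane2 (aka Rsg1)		CLO	Homozygous mutants show CL. Mutation is ENU-induced single point mutation.	25807483	
single-07	single	Ctnnb1		CLP	Pitx1-Cre;Ctnnb1 dex3/dex3 cKO (gain of function) and Pitx1-Cre;Ctnnb1 dex2-6/dex2-6 cKO (loss of function) mice show CL and CP.	22354888	
single-08	single	Dzip1l		CLP	Homozygous null mutant mice show bilateral CL and CP.	28530676	
single-09	single	Ednrb		CLP or CPO	Homozygous null mutant mice show CL at 27% and CP at 83%.	8722795;17693063	
single-10	single	Ermp1		CLP	Homozygous mutant mice show CL and CP. Mutation is ENU-induced single point mutation.	25807483	
single-11	single	Esrp1		CLP	Homozygous null mutant mice show CL and CP at 100%.	26371508	
single-12	single	Ext1		CLP	Wnt1-Cre;Ext1 cKO mice show CL and CP.	19509472	
single-13	single	Folr1 (aka Folbp1)		CLP or CLO	Homozygous null mutant mice show bilateral CL at 43%, unilateral CL at 32%, and CP at 51%. Some embryos show failure of the mandibular process, resulting in mandibular cleft.	12854656	
single-14	single	Gldc		midfacial cleft or CLP	Homozygous mutant mice show midfacial cleft or CL and CP. Mutation is ENU-induced single point mutation.	25807483	
single-15	single	Kif7		CLO, CLP, or CPO	Homozygous mutant mice show CL or CP. Mutation is ENU-induced single point mutation.	25807483	
single-16	single	Lgl		CLP or midfacial cleft and CP	Lgl Tg/Tg (deletion transgenic) mice show midfacial cleft or CL and CP at 40%.	3406741;2313245	
single-17	single	Lrp6		CLP	Homozygous null mutant mice show either bilateral or unilateral CL and CP at 100%.	19700620;19653321	
single-18	single	Mirc1 (aka miR-17-92)		CLP	Homozygous null mutant mice show bilateral CL/P at 32.4% and unilateral CL/P at 17.7%. 44% of mutant mice show mandibular cleft.	24068957	
single-19	single	Mks1		CLO, CLP, or CPO	Homozygous null mutant mice show CL and/or CP.	21045211;23454480	
single-20	single	Myh10		CLO	Homozygous mutant mice show CL. Mutation is ENU-induced single point mutation.	25807483	
single-21	single	Nosip		CLP, midfacial cleft and CP	Nosip null mice exhibit unilateral CL and CP (48.6%; as a mild phenotype) and midfacial cleft with CP (28.6%; as a severe phenotype).	25546391	
single-22	single	Pbx1		CLO, CLP, or CPO	Foxg1-Cre;Pbx1 cKO mice show CPO at 33%, either unilateral or bilateral CL and CP at 62%, and unilateral CLO at 5%.	29797482	
single-23	single	Ph		midfacial cleft, CLO, or CLP	Homozygous mutant mice show facial cleft or CL.		Rasberry and Cattanach, 1994 Mouse Genome, 92 (3):504-505
single-24	single	Porcn		CLO or CLP	Wnt1-Cre;Porcn F/Y cKO mice show CL at 100% and CP. Rx3-Cre;Porcn F/Y cKO mice show bilateral CL and CP. Wnt1-Cre;Rx3-Cre;Porcn F/Y cKO mice show CL and CP at 100%.	25451153	
single-25	single	Ptch1		CL or midfacial cleft	Wnt1-Cre;Ptch1 cKO mice show CL or midfacial cleft at E12.5. Embryos die by E12.5.	23900075	
single-26	single	Ptpn11		CLP	Wnt1-Cre;Ptpn11 Tg/+ (gain of function) mice show CL and CP at 21%.	19706403	
single-27	single	Rpgrip1l		CLO	Homozygous null mutant mice show CL.	17553904;17558409;21677750	
single-28	single	Satb2		CLP	Homozygous null mutant mice show CL and CP.	16960803;16751105	
single-29	single	Sox11		CLP or CPO	Homozygous null mutant mice and EIIa-Cre;Sox11 cKO mice show either unilateral or bilateral CL at 70% and either anterior or complete CP at 100%.	15254231;26826126	
single-30	single	Sp8		CLO	FoxG1-Cre;Sp8 cKO mice (5 out of 13) exhibit CLO.	23872235	
single-31	single	Tbc1d32		CLO or CLP	Homozygous mutant mice show CL and CP. Mutation is ENU-induced single point mutation.	25807483	
single-32	single	Tbx1		CLO or CLP	Ap2a IRESCre/+;COET conditional Tbx1 overexpression mice exhibit bilateral CL. No information about CP.	19557177	
single-33	single	Tfap2a		CLP	Tfap2a null/neo mice show bilateral CL and CP at 100%.	25381013	
single-34	single	Tgfbr1 (aka Alk5)		CLO or CLP	Nestin-Cre;Tgfbr1 cKO mice show either unilateral or bilateral CL at 64%. No information about CP.	18586087	
single-35	single	Tmem107		CLP	Homozygous mutant mice show CL and CP at 14%.	22698544;28954202	
single-36	single	Trp53		CLP	CMV-Cre;Trp53 LSL-25.26.53.54/+ mice show CL and CP.	25119037	
single-37	single	Trp63		CLP	Homozygous null mutant mice show bilateral CL and CP at 100%.	18634775	
single-38	single	Wdr19 (aka Ift144)		CLP	Homozygous mutant mice show bilateral CL and CP. Mutation is ENU-induced single point mutation.	22228095	
single-39	single	Wnt9b		CLO or CLP	Foxg1-Cre/+;Wnt9b cKO mice show bilateral CL at 59% and CP.	21982646	
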