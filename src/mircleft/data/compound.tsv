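record_id	table_kind	gene_symbols	aliases	cleft_type	penetrance_note	pmids	note
compound-01	compound	Bbs7;Ift88		CLO or CLP	Bbs7 -/-;Ift88 orpk double mutant mice exhibit CL at E12.5. The single mutant mice do not show CL nor CP. Ift88 orpk is a hypomorphic allele.	22228099	
compound-02	compound	Fgf8;Tfap2a		CLP	Tfap2a null/neo;Fgf8 +/- mice show bilateral CL and CP in 10/18 and unilateral CL/P in 8/10. This compound mutant mouse is a rescue model of Tfap2a null/neo mice.	25381013	
compound-03	compound	Gdf1;Nodal		CLO	Gdf1 -/-;Nodal +/- mutant mice show CL at 68% at E13.5.	16564040	
compound-04	compound	Hhat;Ptch1		CLP	Hhat Tg(Tfap2a-Cre)/+;Ptch1 +/- double heterozygous mice show CL and primary palate cleft at E12.5.	24590292	
compound-05	compound	Lrp6;Rspo2		CLP or CPO	Lrp6 +/-;Rspo2 -/- mutant mice show CL and CP in 1/6 or CPO in 5/6.	21237142	
compound-06	compound	Mirc1 (aka miR-17-92);Mirc3 (aka miR-106b-25)		CLP	Mirc1 null/null;Mirc3 null/null mutant mice show bilateral CL and CP in 100%, and mandibular cleft at 100%. Mirc1 null/null;Mirc3 null/+ mutant mice show bilateral CL/P in 67.5% and unilateral CL/P at 12.5%, and mandibular cleft at 57.5%.	24068957	
compound-07	compound	Msx1;Pax9		CLP or CPO	Msx1 -/-;Pax9 -/- double KO mice show either unilateral or bilateral CL at 39%, CP and midfacial hypoplasia at 100%.	20123092	
compound-08	compound	Pbx1;Pbx2		CLO, CLP, or CPO	Foxg1-Cre;Pbx1 F/F;Pbx2 -/- double cKO mice show bilateral CL. Foxg1-Cre;Pbx1 F/F;Pbx2 +/- mice show bilateral CL and CP. Pbx1 -/-;Pbx2 +/- mutant mice show CL and CP.	21982646	
compound-09	compound	Pbx1;Wnt9b		CLO or CLP	Foxg1-Cre;Pbx1 +/-;Wnt9b F/F mice show bilateral CL at 100% and CP.	21982646	
compound-10	compound	Pbx1;Pbx3		CLO, CLP, or CPO	Pbx1 -/-;Pbx3 +/- mutant mice show either unilateral or bilateral CL and/or CP. Tcfap2a-Cre;Pbx1 F/F;Pbx3 +/- mutants show CL and/or CP.	21982646	
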