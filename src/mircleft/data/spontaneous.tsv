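record_id	table_kind	gene_symbols	aliases	cleft_type	penetrance_note	pmids	note
spont-01	spontaneous	Clf2		CLP	Homozygous mutant mice show CL and CP at higher incidence.	7601909	
spont-02	spontaneous	Rpl38		CLO, CLP, or CPO	Heterozygous mutant mice show CL and/or CP.	10889952;21529712	
spont-03	spontaneous	Tbx10		CLP	Homozygous Tbx10 Tg/Tg (gain of function) mice show either unilateral or bilateral CL and CP.	5297683;15118109	
spont-04	spontaneous	Wnt9b (aka Clf1)		CLO or CLP	Homozygous null mutant mice show either unilateral or bilateral CL with/without CP.	16998816	
spont-05	spontaneous	Zeb1		CLP	Homozygous mutant mice show either unilateral or bilateral and either complete or incomplete CL and CP. Twirler is mouse line name.	13539273;10669096	
spont-06	spontaneous			CLO or CLP	10% mice show CL/P.	7202260	Not gene; strain A/HeJ
spont-07	spontaneous			CLO or CLP	10% mice show CL/P.	7202260;7394720	Not gene; strain A/J
spont-08	spontaneous			CLO or CLP	20-30% mice show CL/P.	7202260	Not gene; strain A/Wysn
spont-09	spontaneous			CLO or CLP	20-40% mice show CL/P. The cleft frequency depends on the colony.	5538410;7102571;7394720	Not gene; strain CL/Fr
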