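mirna	n_genes	genes	p_value	fdr
mmu-miR-200a-3p	10	Ctnnb1,Myh10,Zeb1,Esrp1,Pbx1,Ptch1,Satb2,Sox11,Tfap2a,Tgfbr1	3.00E-05	0.053
mmu-miR-141-3p	9	Myh10,Zeb1,Esrp1,Pbx1,Ptch1,Satb2,Sox11,Tfap2a,Tgfbr1	1.74E-04	0.062
mmu-miR-196a-5p	6	Ednrb,Pbx1,Pbx3,Rpgrip1l,Rspo2,Sox11	1.41E-04	0.062
mmu-miR-196b-5p	6	Ednrb,Pbx1,Pbx3,Rpgrip1l,Rspo2,Sox11	1.41E-04	0.062
mmu-miR-710	6	Cdc42,Ctnnb1,Pbx3,Rpgrip1l,Satb2,Sp8	1.29E-04	0.062
mmu-miR-101a-3p	10	Cdc42,Msx1,Pax9,Pbx3,Ptch1,Rspo2,Sox11,Tbx1,Tgfbr1,Zeb1	4.77E-04	0.072
mmu-miR-101b-3p	9	Cdc42,Msx1,Pbx3,Ptch1,Rspo2,Sox11,Tbx1,Tgfbr1,Zeb1	5.31E-04	0.072
mmu-miR-144-3p	9	Msx1,Pbx3,Ptch1,Rpgrip1l,Rspo2,Sox11,Tbx1,Tgfbr1,Zeb1	2.72E-04	0.072
mmu-let-7a-1-3p	5	Bmpr1a,Cdc42,Ctnnb1,Lrp6,Ptch1	5.25E-04	0.072
mmu-let-7b-3p	5	Bmpr1a,Cdc42,Ctnnb1,Lrp6,Ptch1	5.25E-04	0.072
mmu-let-7c-2-3p	5	Bmpr1a,Cdc42,Ctnnb1,Lrp6,Ptch1	5.25E-04	0.072
mmu-let-7f-1-3p	5	Bmpr1a,Cdc42,Ctnnb1,Lrp6,Ptch1	5.25E-04	0.072
mmu-miR-98-3p	5	Bmpr1a,Cdc42,Ctnnb1,Lrp6,Ptch1	5.25E-04	0.072
mmu-miR-181a-5p	11	Ednrb,Ermp1,Ptch1,Ptpn11,Myh10,Pax9,Pbx1,Pbx3,Rspo2,Sox11,Tgfbr1	7.27E-04	0.081
mmu-miR-466 l	13	Bmp4,Dzip1l,Lrp6,Pax9,Pbx1,Pbx3,Ptpn11,Rspo2,Satb2,Sox11,Tbx1,Wnt9b,Zeb1	1.26E-03	0.118
mmu-miR-686	5	Pbx1,Rpgrip1l,Tgfbr1,Zeb1,Ptch1	1.40E-03	0.124
mmu-miR-320-3p	7	Bmpr1a,Ctnnb1,Lrp6,Pbx1,Pbx3,Satb2,Tgfbr1	1.49E-03	0.126
mmu-miR-205-5p	6	Ext1,Lrp6,Pax9,Pbx1,Satb2,Zeb1	1.62E-03	0.131
mmu-miR-491	14	Cdc42,Ermp1,Esrp1,Fgf8,Kif7,Mks1,Myh10,Pax9,Pbx2,Tbx10,Wdr19,Wnt9b,Zeb1,Sox11	1.76E-03	0.136
mmu-miR-142a-3p	7	Bmpr1a,Ctnnb1,Myh10,Sox11,Sp8,Tgfbr1,Zeb1	2.45E-03	0.139
mmu-miR-302c	5	Ednrb,Pbx3,Tgfbr1,Wnt9b,Zeb1	2.39E-03	0.139
mmu-miR-669b	5	Cdc42,Ext1,Pbx2,Rpgrip1l,Sox11	2.39E-03	0.139
mmu-miR-669f	9	Cdc42,Gldc,Msx1,Pax9,Pbx1,Pbx3,Rspo2,Satb2,Tgfbr1	2.05E-03	0.139
mmu-miR-124	16	Bmpr1a,Ctnnb1,Ednrb,Esrp1,Folr1,Gldc,Hhat,Ift88,Lrp6,Myh10,Pax9,Pbx1,Ptpn11,Rspo2,Zeb1,Tgfbr1	2.91E-03	0.149
mmu-miR-124-3p	13	Cdc42,Pbx3,Sp8,Bmpr1a,Ednrb,Ermp1,Esrp1,Ift88,Lrp6,Myh10,Ptpn11,Tgfbr1,Zeb1	2.95E-03	0.149
mmu-miR-374c-5p	7	Esrp1,Myh10,Pbx3,Ptch1,Ptpn11,Sp8,Zeb1	3.34E-03	0.165
mmu-miR-425-5p	6	Pbx1,Ptch1,Ptpn11,Rpgrip1l,Tgfbr1,Satb2	3.79E-03	0.174
mmu-miR-673-5p	5	Sox11,Ctnnb1,Pax9,Rpgrip1l,Sp8	3.81E-03	0.174
mmu-miR-142-5p	6	Cdc42,Ctnnb1,Pax9,Pbx3,Rpgrip1l,Trp63	3.64E-03	0.174
mmu-miR-543-3p	6	Ermp1,Myh10,Pbx1,Pbx3,Ptch1,Rspo2	4.58E-03	0.194
mmu-miR-340-5p	24	Bbs7,Bmp4,Bmpr1a,Cdc42,Ermp1,Esrp1,Gldc,Lrp6,Mks1,Msx1,Pbx1,Pbx2,Pbx3,Rpgrip1l,Rspo2,Sox11,Tgfbr1,Tmem107,Trp53,Trp63,Wdr19,Zeb1,Myh10,Ptch1	4.98E-03	0.198
mmu-miR-23a-3p	8	Ednrb,Esrp1,Pax9,Pbx1,Rpgrip1l,Satb2,Sox11,Zeb1	5.13E-03	0.198
mmu-miR-23b-3p	8	Ednrb,Esrp1,Pax9,Pbx1,Rpgrip1l,Satb2,Sox11,Zeb1	5.07E-03	0.198
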