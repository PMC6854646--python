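gene	n_mirnas	mirnas
Zeb1	17	miR-124,miR-340-5p,miR-491,miR-101a-3p,miR-101b-3p,miR-124-3p,miR-141-3p,miR-142a-3p,miR-144-3p,miR-200a-3p,miR-205-5p,miR-23a-3p,miR-23b-3p,miR-374c-5p,miR-686,miR-302c,miR-466 l
Pbx1	16	miR-124,miR-340-5p,miR-141-3p,miR-181a-5p,miR-196a-5p,miR-196b-5p,miR-200a-3p,miR-205-5p,miR-23a-3p,miR-23b-3p,miR-320-3p,miR-425-5p,miR-543-3p,miR-686,miR-466 l,miR-669f
Pbx3	16	miR-340-5p,miR-101a-3p,miR-101b-3p,miR-124-3p,miR-144-3p,miR-181a-5p,miR-196a-5p,miR-196b-5p,miR-320-3p,miR-374c-5p,miR-543-3p,miR-710,miR-142-5p,miR-302c,miR-466 l,miR-669f
Ptch1	16	miR-340-5p,miR-101a-3p,miR-101b-3p,miR-141-3p,miR-144-3p,miR-181a-5p,miR-200a-3p,miR-374c-5p,miR-425-5p,miR-543-3p,miR-686,let-7a-1-3p,let-7b-3p,let-7c-2-3p,let-7f-1-3p,miR-98-3p
Sox11	16	miR-340-5p,miR-491,miR-101a-3p,miR-101b-3p,miR-141-3p,miR-142a-3p,miR-144-3p,miR-181a-5p,miR-196a-5p,miR-196b-5p,miR-200a-3p,miR-23a-3p,miR-23b-3p,miR-673-5p,miR-466 l,miR-669b
Tgfbr1	15	miR-124,miR-340-5p,miR-101a-3p,miR-101b-3p,miR-124-3p,miR-141-3p,miR-142a-3p,miR-144-3p,miR-181a-5p,miR-200a-3p,miR-320-3p,miR-425-5p,miR-686,miR-302c,miR-669f
Cdc42	14	miR-340-5p,miR-491,miR-101a-3p,miR-101b-3p,miR-124-3p,miR-710,miR-142-5p,miR-669b,miR-669f,let-7a-1-3p,let-7b-3p,let-7c-2-3p,let-7f-1-3p,miR-98-3p
Ctnnb1	12	miR-124,miR-142a-3p,miR-200a-3p,miR-320-3p,miR-673-5p,miR-710,miR-142-5p,let-7a-1-3p,let-7b-3p,let-7c-2-3p,let-7f-1-3p,miR-98-3p
Rpgrip1l	12	miR-340-5p,miR-144-3p,miR-196a-5p,miR-196b-5p,miR-23a-3p,miR-23b-3p,miR-425-5p,miR-673-5p,miR-686,miR-710,miR-142-5p,miR-669b
Lrp6	11	miR-124,miR-340-5p,miR-124-3p,miR-205-5p,miR-320-3p,miR-466 l,let-7a-1-3p,let-7b-3p,let-7c-2-3p,let-7f-1-3p,miR-98-3p
Pax9	11	miR-124,miR-491,miR-101a-3p,miR-181a-5p,miR-205-5p,miR-23a-3p,miR-23b-3p,miR-673-5p,miR-142-5p,miR-466 l,miR-669f
Rspo2	11	miR-124,miR-340-5p,miR-101a-3p,miR-101b-3p,miR-144-3p,miR-181a-5p,miR-196a-5p,miR-196b-5p,miR-543-3p,miR-466 l,miR-669f
Bmpr1a	10	miR-124,miR-340-5p,miR-124-3p,miR-142a-3p,miR-320-3p,let-7a-1-3p,let-7b-3p,let-7c-2-3p,let-7f-1-3p,miR-98-3p
Myh10	10	miR-124,miR-340-5p,miR-491,miR-124-3p,miR-141-3p,miR-142a-3p,miR-181a-5p,miR-200a-3p,miR-374c-5p,miR-543-3p
Satb2	10	miR-141-3p,miR-200a-3p,miR-205-5p,miR-23a-3p,miR-23b-3p,miR-320-3p,miR-425-5p,miR-710,miR-466 l,miR-669f
Esrp1	9	miR-124,miR-340-5p,miR-491,miR-124-3p,miR-141-3p,miR-200a-3p,miR-23a-3p,miR-23b-3p,miR-374c-5p
Ednrb	8	miR-124,miR-124-3p,miR-181a-5p,miR-196a-5p,miR-196b-5p,miR-23a-3p,miR-23b-3p,miR-302c
Ptpn11	6	miR-124,miR-124-3p,miR-181a-5p,miR-374c-5p,miR-425-5p,miR-466 l
Ermp1	5	miR-340-5p,miR-491,miR-124-3p,miR-181a-5p,miR-543-3p
Msx1	5	miR-340-5p,miR-101a-3p,miR-101b-3p,miR-144-3p,miR-669f
Sp8	5	miR-124-3p,miR-142a-3p,miR-374c-5p,miR-673-5p,miR-710
Tbx1	4	miR-101a-3p,miR-101b-3p,miR-144-3p,miR-466 l
Gldc	3	miR-124,miR-340-5p,miR-669f
Pbx2	3	miR-340-5p,miR-491,miR-669b
Wnt9b	3	miR-491,miR-302c,miR-466 l
Bmp4	2	miR-340-5p,miR-466 l
Ext1	2	miR-205-5p,miR-669b
Ift88	2	miR-124,miR-124-3p
Mks1	2	miR-340-5p,miR-491
Tfap2a	2	miR-141-3p,miR-200a-3p
Trp63	2	miR-340-5p,miR-142-5p
Wdr19	2	miR-340-5p,miR-491
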