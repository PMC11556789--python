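name	length	n_pos	n_neg	net_charge	n_aromatic	observed_class	bold_chg	bold_net	bold_aro	notes
FIB-1	352	55	34	21	24	screening	1	0	0
PolyQ	729	38	34	4	35	screening	0	0	0
Ddx4	236	32	36	-4	22	screening	1	0	1
HP1a	206	33	41	-8	14	screening	1	0	0
LAF-1	708	86	88	-2	55	screening	1	0	0
LAF-1 RGG	191	28	22	6	14	screening	1	0	0
Oleo30G	139	15	12	3	7	screening	0	0	0
FMRP-LCD	188	37	28	9	6	screening	1	0	0
hnRNPA1	314	42	34	8	33	screening	1	0	1
pY-Caprin1	103	16	17	-1	4	screening	1	0	0	phospho-Tyr; charge units
FUS	526	51	37	14	52	reentrant	0	0	1
TDP-43	414	40	44	-4	36	reentrant	1	0	1
Brd4	1362	175	150	25	48	reentrant	1	0	0
Sox2	317	34	21	13	19	reentrant	0	0	0
A11	505	51	50	1	41	reentrant	1	0	1
A1-LCD	131	12	3	9	18	high_net_charge	0	1	1
Lysozyme	129	17	9	8	12	high_net_charge	1	1	1	folded domain
RMFP-1	121	24	0	24	24	high_net_charge	0	1	1
UBQLN2	624	31	40	-9	22	high_net_charge	0	0	0
UBQLN2 (450-624)	175	4	8	-4	5	high_net_charge	0	0	0
TDP43-LCD (pH 4)	148	14	3	11	12	high_net_charge	0	1	1	low pH; His protonated
HBP-2 (pH 5.5)	193	30	13	17	20	high_net_charge	1	1	1	low pH; His protonated
Caprin1	103	16	3	13	11	high_net_charge	0	1	1
Prp-LCD	122	11	1	10	11	high_net_charge	0	1	1
RLP3_8	120	12	8	4	8	high_net_charge	0	0	0
FUS-LCD	136	0	2	-2	20	low_net_charge	0	0	1
TDP43-LCD (pH 7)	148	8	3	5	12	low_net_charge	0	0	1
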