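protein_id	disulfide_bond_count
ALB_SYN	17
TF_SYN	19
IGG_SYN	16
IGA_SYN	22
IGM_SYN	31
IGD_SYN	13
IGE_SYN	24
FIB_SYN	29
HP_SYN	5
A1AT_SYN	0
BSA_SYN	17
BLG_SYN	2
LYZ	4
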