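# Compact polar-hydrogen partial-charge set (CHARMM22-informed), version compact-1.0
# resname	state	atom	charge
# resname '*' = amino-acid backbone applied to every standard residue;
# atom '*' = wildcard for any atom of the residue not otherwise covered.
*	bg	N	-0.35
*	bg	H	0.25
*	bg	CA	0.10
*	bg	C	0.55
*	bg	O	-0.55
ALA	bg	CB	0.00
GLY	bg	*	0.00
SER	bg	CB	0.25
SER	bg	OG	-0.66
SER	bg	HG	0.41
THR	bg	CB	0.25
THR	bg	OG1	-0.66
THR	bg	HG1	0.41
THR	bg	CG2	0.00
ASN	bg	CB	0.00
ASN	bg	CG	0.55
ASN	bg	OD1	-0.55
ASN	bg	ND2	-0.60
ASN	bg	HD21	0.30
ASN	bg	HD22	0.30
ASP	bg	CB	0.00
ASP	ASP_prot	CG	0.48
ASP	ASP_prot	OD1	-0.24
ASP	ASP_prot	OD2	-0.24
ASP	ASP_deprot	CG	0.48
ASP	ASP_deprot	OD1	-0.74
ASP	ASP_deprot	OD2	-0.74
GLU	bg	CB	0.00
GLU	bg	CG	0.00
GLU	GLU_prot	CD	0.48
GLU	GLU_prot	OE1	-0.24
GLU	GLU_prot	OE2	-0.24
GLU	GLU_deprot	CD	0.48
GLU	GLU_deprot	OE1	-0.74
GLU	GLU_deprot	OE2	-0.74
LYS	bg	CB	0.00
LYS	bg	CG	0.00
LYS	bg	CD	0.00
LYS	bg	CE	0.00
LYS	LYS_prot	NZ	-0.20
LYS	LYS_prot	HZ1	0.40
LYS	LYS_prot	HZ2	0.40
LYS	LYS_prot	HZ3	0.40
LYS	LYS_deprot	NZ	-0.20
LYS	LYS_deprot	HZ1	0.0666666666667
LYS	LYS_deprot	HZ2	0.0666666666667
LYS	LYS_deprot	HZ3	0.0666666666667
ARG	bg	CB	0.00
ARG	bg	CG	0.00
ARG	bg	CD	0.00
ARG	ARG_prot	NE	-0.50
ARG	ARG_prot	HE	0.42
ARG	ARG_prot	CZ	0.60
ARG	ARG_prot	NH1	-0.60
ARG	ARG_prot	HH11	0.42
ARG	ARG_prot	HH12	0.42
ARG	ARG_prot	NH2	-0.60
ARG	ARG_prot	HH21	0.42
ARG	ARG_prot	HH22	0.42
ARG	ARG_deprot	NE	-0.50
ARG	ARG_deprot	HE	0.22
ARG	ARG_deprot	CZ	0.60
ARG	ARG_deprot	NH1	-0.60
ARG	ARG_deprot	HH11	0.22
ARG	ARG_deprot	HH12	0.22
ARG	ARG_deprot	NH2	-0.60
ARG	ARG_deprot	HH21	0.22
ARG	ARG_deprot	HH22	0.22
CYS	bg	CB	0.10
CYS	CYS_prot	SG	-0.30
CYS	CYS_prot	HG	0.20
CYS	CYS_deprot	SG	-1.10
CYS	CYS_deprot	HG	0.00
TYR	bg	CB	0.00
TYR	bg	CG	0.00
TYR	bg	CD1	0.00
TYR	bg	CD2	0.00
TYR	TYR_prot	CE1	0.00
TYR	TYR_prot	CE2	0.00
TYR	TYR_prot	CZ	0.25
TYR	TYR_prot	OH	-0.60
TYR	TYR_prot	HH	0.35
TYR	TYR_deprot	CE1	-0.10
TYR	TYR_deprot	CE2	-0.10
TYR	TYR_deprot	CZ	0.10
TYR	TYR_deprot	OH	-0.90
TYR	TYR_deprot	HH	0.00
HIS	bg	CB	0.00
HIS	bg	CG	0.10
HIS	bg	CD2	0.10
HIS	bg	CE1	0.20
HIS	HIS_ND1_prot	ND1	-0.10
HIS	HIS_ND1_prot	HD1	0.40
HIS	HIS_ND1_deprot	ND1	-0.70
HIS	HIS_ND1_deprot	HD1	0.00
HIS	HIS_NE2_prot	NE2	-0.10
HIS	HIS_NE2_prot	HE2	0.40
HIS	HIS_NE2_deprot	NE2	-0.70
HIS	HIS_NE2_deprot	HE2	0.00
HOH	bg	O	-0.834
HOH	bg	H1	0.417
HOH	bg	H2	0.417
TTA	TTA_prot	O1	0.00
TTA	TTA_deprot	O1	-1.00
TTB	TTB_prot	N1	1.00
TTB	TTB_deprot	N1	0.00
TTR	TTR_red	FE	0.00
TTR	TTR_ox	FE	1.00
CFA	neutral	*	0.00
CFB	neutral	*	0.00
MAT	bg	*	0.00
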