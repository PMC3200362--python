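# Polar-hydrogen topology: ideal internal coordinates.
# dihedral is measured over r2-r1-parent-H; for rotor groups it is the offset
# within the rotor, whose base torsion is scanned on a 15-degree grid.
# resname	hname	parent	r1	r2	bond	angle	dihedral	rotor
GLY	H	N	CA	C	1.01	118	180	-
ALA	H	N	CA	C	1.01	118	180	-
SER	H	N	CA	C	1.01	118	180	-
THR	H	N	CA	C	1.01	118	180	-
ASN	H	N	CA	C	1.01	118	180	-
ASP	H	N	CA	C	1.01	118	180	-
GLU	H	N	CA	C	1.01	118	180	-
LYS	H	N	CA	C	1.01	118	180	-
ARG	H	N	CA	C	1.01	118	180	-
CYS	H	N	CA	C	1.01	118	180	-
TYR	H	N	CA	C	1.01	118	180	-
HIS	H	N	CA	C	1.01	118	180	-
SER	HG	OG	CB	CA	0.96	109.5	0	rot
THR	HG1	OG1	CB	CA	0.96	109.5	0	rot
TYR	HH	OH	CZ	CE1	0.96	109.5	0	rot
CYS	HG	SG	CB	CA	1.34	96	0	rot
LYS	HZ1	NZ	CE	CD	1.01	109.5	0	rot
LYS	HZ2	NZ	CE	CD	1.01	109.5	120	rot
LYS	HZ3	NZ	CE	CD	1.01	109.5	240	rot
ARG	HE	NE	CZ	NH1	1.01	120	180	-
ARG	HH11	NH1	CZ	NE	1.01	120	0	-
ARG	HH12	NH1	CZ	NE	1.01	120	180	-
ARG	HH21	NH2	CZ	NE	1.01	120	0	-
ARG	HH22	NH2	CZ	NE	1.01	120	180	-
ASN	HD21	ND2	CG	OD1	1.01	120	180	-
ASN	HD22	ND2	CG	OD1	1.01	120	0	-
HIS	HD1	ND1	CG	CD2	1.01	126	180	-
HIS	HE2	NE2	CE1	ND1	1.01	126	180	-
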