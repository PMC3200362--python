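# Titratable-site definitions.
# ref_value: reference pKa (pH units) for acid/base, reference midpoint (mV) for redox.
# ref_is: which member of the pair is the site's neutral reference state.
# proton_atoms: hydrogens physically absent in the deprotonated form ('-' = none;
#   charge-smeared deprotonation keeps all protons in place).
# resname	subsite	kind	ref_value	prot_state	deprot_state	ref_is	proton_atoms
ASP	-	acid	4.0	ASP_prot	ASP_deprot	prot	-
GLU	-	acid	4.4	GLU_prot	GLU_deprot	prot	-
CYS	-	acid	9.5	CYS_prot	CYS_deprot	prot	HG
TYR	-	acid	9.6	TYR_prot	TYR_deprot	prot	HH
LYS	-	base	10.4	LYS_prot	LYS_deprot	deprot	-
ARG	-	base	12.0	ARG_prot	ARG_deprot	deprot	-
HIS	ND1	acid	6.6	HIS_ND1_prot	HIS_ND1_deprot	prot	HD1
HIS	NE2	base	7.0	HIS_NE2_prot	HIS_NE2_deprot	deprot	HE2
TTA	-	acid	5.0	TTA_prot	TTA_deprot	prot	-
TTB	-	base	9.0	TTB_prot	TTB_deprot	deprot	-
TTR	-	redox	100.0	TTR_red	TTR_ox	prot	-
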