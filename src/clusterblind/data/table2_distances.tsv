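# Metal-to-proton distances (A) for the cluster-binding residues of human
# mitoNEET (crystal-structure numbering; Cys-72/Cys-74 coordinate Fe1,
# Cys-83/His-87 coordinate Fe2). The bonds column is the number of covalent
# bonds from the proton to the coordinating iron, derived from standard
# amino-acid topology (Cys: H-N-CA-CB-SG-Fe; His via ND1), not read from
# a structure file.
chain	resnum	resname	atom	fe_label	r_angstrom	bonds
A	72	CYS	H	FE1	5.54	5
A	72	CYS	HA	FE1	3.21	4
A	72	CYS	HB2	FE1	3.47	3
A	72	CYS	HB3	FE1	4.35	3
A	74	CYS	H	FE1	3.54	5
A	74	CYS	HA	FE1	4.90	4
A	74	CYS	HB2	FE1	4.25	3
A	74	CYS	HB3	FE1	3.27	3
A	83	CYS	H	FE2	5.61	5
A	83	CYS	HA	FE2	3.39	4
A	83	CYS	HB2	FE2	3.33	3
A	83	CYS	HB3	FE2	4.32	3
A	87	HIS	H	FE2	3.16	6
A	87	HIS	HA	FE2	4.99	5
A	87	HIS	HB2	FE2	4.39	4
A	87	HIS	HB3	FE2	2.98	4
A	87	HIS	HE1	FE2	3.06	3
A	87	HIS	HE2	FE2	4.94	4
A	87	HIS	HD2	FE2	5.18	4
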