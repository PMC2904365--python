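# groovedock atom parameter table v1
# radius: NACCESS-style united-atom radii (Angstrom); charge: simplified formal charges (e); eps/rmin_half: Lennard-Jones well depth (kcal/mol) and half minimum-energy distance (Angstrom)
residue	atom	element	radius	charge	eps	rmin_half	donor	acceptor
ALA	N	N	1.65	+0.00	0.170	1.85	1	0
ALA	CA	C	1.87	+0.00	0.110	2.00	0	0
ALA	C	C	1.87	+0.00	0.110	2.00	0	0
ALA	O	O	1.40	+0.00	0.120	1.70	0	1
ALA	OXT	O	1.40	+0.00	0.120	1.70	0	1
ALA	CB	C	1.87	+0.00	0.110	2.00	0	0
ARG	N	N	1.65	+0.00	0.170	1.85	1	0
ARG	CA	C	1.87	+0.00	0.110	2.00	0	0
ARG	C	C	1.87	+0.00	0.110	2.00	0	0
ARG	O	O	1.40	+0.00	0.120	1.70	0	1
ARG	OXT	O	1.40	+0.00	0.120	1.70	0	1
ARG	CB	C	1.87	+0.00	0.110	2.00	0	0
ARG	CG	C	1.87	+0.00	0.110	2.00	0	0
ARG	CD	C	1.87	+0.00	0.110	2.00	0	0
ARG	NE	N	1.65	+0.00	0.170	1.85	1	0
ARG	CZ	C	1.87	+0.00	0.110	2.00	0	0
ARG	NH1	N	1.65	+0.50	0.170	1.85	1	0
ARG	NH2	N	1.65	+0.50	0.170	1.85	1	0
ASN	N	N	1.65	+0.00	0.170	1.85	1	0
ASN	CA	C	1.87	+0.00	0.110	2.00	0	0
ASN	C	C	1.87	+0.00	0.110	2.00	0	0
ASN	O	O	1.40	+0.00	0.120	1.70	0	1
ASN	OXT	O	1.40	+0.00	0.120	1.70	0	1
ASN	CB	C	1.87	+0.00	0.110	2.00	0	0
ASN	CG	C	1.87	+0.00	0.110	2.00	0	0
ASN	OD1	O	1.40	+0.00	0.120	1.70	0	1
ASN	ND2	N	1.65	+0.00	0.170	1.85	1	0
ASP	N	N	1.65	+0.00	0.170	1.85	1	0
ASP	CA	C	1.87	+0.00	0.110	2.00	0	0
ASP	C	C	1.87	+0.00	0.110	2.00	0	0
ASP	O	O	1.40	+0.00	0.120	1.70	0	1
ASP	OXT	O	1.40	+0.00	0.120	1.70	0	1
ASP	CB	C	1.87	+0.00	0.110	2.00	0	0
ASP	CG	C	1.87	+0.00	0.110	2.00	0	0
ASP	OD1	O	1.40	-0.50	0.120	1.70	0	1
ASP	OD2	O	1.40	-0.50	0.120	1.70	0	1
CYS	N	N	1.65	+0.00	0.170	1.85	1	0
CYS	CA	C	1.87	+0.00	0.110	2.00	0	0
CYS	C	C	1.87	+0.00	0.110	2.00	0	0
CYS	O	O	1.40	+0.00	0.120	1.70	0	1
CYS	OXT	O	1.40	+0.00	0.120	1.70	0	1
CYS	CB	C	1.87	+0.00	0.110	2.00	0	0
CYS	SG	S	1.85	+0.00	0.450	2.00	1	0
GLN	N	N	1.65	+0.00	0.170	1.85	1	0
GLN	CA	C	1.87	+0.00	0.110	2.00	0	0
GLN	C	C	1.87	+0.00	0.110	2.00	0	0
GLN	O	O	1.40	+0.00	0.120	1.70	0	1
GLN	OXT	O	1.40	+0.00	0.120	1.70	0	1
GLN	CB	C	1.87	+0.00	0.110	2.00	0	0
GLN	CG	C	1.87	+0.00	0.110	2.00	0	0
GLN	CD	C	1.87	+0.00	0.110	2.00	0	0
GLN	OE1	O	1.40	+0.00	0.120	1.70	0	1
GLN	NE2	N	1.65	+0.00	0.170	1.85	1	0
GLU	N	N	1.65	+0.00	0.170	1.85	1	0
GLU	CA	C	1.87	+0.00	0.110	2.00	0	0
GLU	C	C	1.87	+0.00	0.110	2.00	0	0
GLU	O	O	1.40	+0.00	0.120	1.70	0	1
GLU	OXT	O	1.40	+0.00	0.120	1.70	0	1
GLU	CB	C	1.87	+0.00	0.110	2.00	0	0
GLU	CG	C	1.87	+0.00	0.110	2.00	0	0
GLU	CD	C	1.87	+0.00	0.110	2.00	0	0
GLU	OE1	O	1.40	-0.50	0.120	1.70	0	1
GLU	OE2	O	1.40	-0.50	0.120	1.70	0	1
GLY	N	N	1.65	+0.00	0.170	1.85	1	0
GLY	CA	C	1.87	+0.00	0.110	2.00	0	0
GLY	C	C	1.87	+0.00	0.110	2.00	0	0
GLY	O	O	1.40	+0.00	0.120	1.70	0	1
GLY	OXT	O	1.40	+0.00	0.120	1.70	0	1
HIS	N	N	1.65	+0.00	0.170	1.85	1	0
HIS	CA	C	1.87	+0.00	0.110	2.00	0	0
HIS	C	C	1.87	+0.00	0.110	2.00	0	0
HIS	O	O	1.40	+0.00	0.120	1.70	0	1
HIS	OXT	O	1.40	+0.00	0.120	1.70	0	1
HIS	CB	C	1.87	+0.00	0.110	2.00	0	0
HIS	CG	C	1.87	+0.00	0.110	2.00	0	0
HIS	ND1	N	1.65	+0.00	0.170	1.85	1	1
HIS	CD2	C	1.87	+0.00	0.110	2.00	0	0
HIS	CE1	C	1.87	+0.00	0.110	2.00	0	0
HIS	NE2	N	1.65	+0.00	0.170	1.85	1	1
ILE	N	N	1.65	+0.00	0.170	1.85	1	0
ILE	CA	C	1.87	+0.00	0.110	2.00	0	0
ILE	C	C	1.87	+0.00	0.110	2.00	0	0
ILE	O	O	1.40	+0.00	0.120	1.70	0	1
ILE	OXT	O	1.40	+0.00	0.120	1.70	0	1
ILE	CB	C	1.87	+0.00	0.110	2.00	0	0
ILE	CG1	C	1.87	+0.00	0.110	2.00	0	0
ILE	CG2	C	1.87	+0.00	0.110	2.00	0	0
ILE	CD1	C	1.87	+0.00	0.110	2.00	0	0
LEU	N	N	1.65	+0.00	0.170	1.85	1	0
LEU	CA	C	1.87	+0.00	0.110	2.00	0	0
LEU	C	C	1.87	+0.00	0.110	2.00	0	0
LEU	O	O	1.40	+0.00	0.120	1.70	0	1
LEU	OXT	O	1.40	+0.00	0.120	1.70	0	1
LEU	CB	C	1.87	+0.00	0.110	2.00	0	0
LEU	CG	C	1.87	+0.00	0.110	2.00	0	0
LEU	CD1	C	1.87	+0.00	0.110	2.00	0	0
LEU	CD2	C	1.87	+0.00	0.110	2.00	0	0
LYS	N	N	1.65	+0.00	0.170	1.85	1	0
LYS	CA	C	1.87	+0.00	0.110	2.00	0	0
LYS	C	C	1.87	+0.00	0.110	2.00	0	0
LYS	O	O	1.40	+0.00	0.120	1.70	0	1
LYS	OXT	O	1.40	+0.00	0.120	1.70	0	1
LYS	CB	C	1.87	+0.00	0.110	2.00	0	0
LYS	CG	C	1.87	+0.00	0.110	2.00	0	0
LYS	CD	C	1.87	+0.00	0.110	2.00	0	0
LYS	CE	C	1.87	+0.00	0.110	2.00	0	0
LYS	NZ	N	1.65	+1.00	0.170	1.85	1	0
MET	N	N	1.65	+0.00	0.170	1.85	1	0
MET	CA	C	1.87	+0.00	0.110	2.00	0	0
MET	C	C	1.87	+0.00	0.110	2.00	0	0
MET	O	O	1.40	+0.00	0.120	1.70	0	1
MET	OXT	O	1.40	+0.00	0.120	1.70	0	1
MET	CB	C	1.87	+0.00	0.110	2.00	0	0
MET	CG	C	1.87	+0.00	0.110	2.00	0	0
MET	SD	S	1.85	+0.00	0.450	2.00	0	1
MET	CE	C	1.87	+0.00	0.110	2.00	0	0
PHE	N	N	1.65	+0.00	0.170	1.85	1	0
PHE	CA	C	1.87	+0.00	0.110	2.00	0	0
PHE	C	C	1.87	+0.00	0.110	2.00	0	0
PHE	O	O	1.40	+0.00	0.120	1.70	0	1
PHE	OXT	O	1.40	+0.00	0.120	1.70	0	1
PHE	CB	C	1.87	+0.00	0.110	2.00	0	0
PHE	CG	C	1.87	+0.00	0.110	2.00	0	0
PHE	CD1	C	1.87	+0.00	0.110	2.00	0	0
PHE	CD2	C	1.87	+0.00	0.110	2.00	0	0
PHE	CE1	C	1.87	+0.00	0.110	2.00	0	0
PHE	CE2	C	1.87	+0.00	0.110	2.00	0	0
PHE	CZ	C	1.87	+0.00	0.110	2.00	0	0
PRO	N	N	1.65	+0.00	0.170	1.85	0	0
PRO	CA	C	1.87	+0.00	0.110	2.00	0	0
PRO	C	C	1.87	+0.00	0.110	2.00	0	0
PRO	O	O	1.40	+0.00	0.120	1.70	0	1
PRO	OXT	O	1.40	+0.00	0.120	1.70	0	1
PRO	CB	C	1.87	+0.00	0.110	2.00	0	0
PRO	CG	C	1.87	+0.00	0.110	2.00	0	0
PRO	CD	C	1.87	+0.00	0.110	2.00	0	0
SER	N	N	1.65	+0.00	0.170	1.85	1	0
SER	CA	C	1.87	+0.00	0.110	2.00	0	0
SER	C	C	1.87	+0.00	0.110	2.00	0	0
SER	O	O	1.40	+0.00	0.120	1.70	0	1
SER	OXT	O	1.40	+0.00	0.120	1.70	0	1
SER	CB	C	1.87	+0.00	0.110	2.00	0	0
SER	OG	O	1.40	+0.00	0.120	1.70	1	1
THR	N	N	1.65	+0.00	0.170	1.85	1	0
THR	CA	C	1.87	+0.00	0.110	2.00	0	0
THR	C	C	1.87	+0.00	0.110	2.00	0	0
THR	O	O	1.40	+0.00	0.120	1.70	0	1
THR	OXT	O	1.40	+0.00	0.120	1.70	0	1
THR	CB	C	1.87	+0.00	0.110	2.00	0	0
THR	OG1	O	1.40	+0.00	0.120	1.70	1	1
THR	CG2	C	1.87	+0.00	0.110	2.00	0	0
TRP	N	N	1.65	+0.00	0.170	1.85	1	0
TRP	CA	C	1.87	+0.00	0.110	2.00	0	0
TRP	C	C	1.87	+0.00	0.110	2.00	0	0
TRP	O	O	1.40	+0.00	0.120	1.70	0	1
TRP	OXT	O	1.40	+0.00	0.120	1.70	0	1
TRP	CB	C	1.87	+0.00	0.110	2.00	0	0
TRP	CG	C	1.87	+0.00	0.110	2.00	0	0
TRP	CD1	C	1.87	+0.00	0.110	2.00	0	0
TRP	CD2	C	1.87	+0.00	0.110	2.00	0	0
TRP	NE1	N	1.65	+0.00	0.170	1.85	1	0
TRP	CE2	C	1.87	+0.00	0.110	2.00	0	0
TRP	CE3	C	1.87	+0.00	0.110	2.00	0	0
TRP	CZ2	C	1.87	+0.00	0.110	2.00	0	0
TRP	CZ3	C	1.87	+0.00	0.110	2.00	0	0
TRP	CH2	C	1.87	+0.00	0.110	2.00	0	0
TYR	N	N	1.65	+0.00	0.170	1.85	1	0
TYR	CA	C	1.87	+0.00	0.110	2.00	0	0
TYR	C	C	1.87	+0.00	0.110	2.00	0	0
TYR	O	O	1.40	+0.00	0.120	1.70	0	1
TYR	OXT	O	1.40	+0.00	0.120	1.70	0	1
TYR	CB	C	1.87	+0.00	0.110	2.00	0	0
TYR	CG	C	1.87	+0.00	0.110	2.00	0	0
TYR	CD1	C	1.87	+0.00	0.110	2.00	0	0
TYR	CD2	C	1.87	+0.00	0.110	2.00	0	0
TYR	CE1	C	1.87	+0.00	0.110	2.00	0	0
TYR	CE2	C	1.87	+0.00	0.110	2.00	0	0
TYR	CZ	C	1.87	+0.00	0.110	2.00	0	0
TYR	OH	O	1.40	+0.00	0.120	1.70	1	1
VAL	N	N	1.65	+0.00	0.170	1.85	1	0
VAL	CA	C	1.87	+0.00	0.110	2.00	0	0
VAL	C	C	1.87	+0.00	0.110	2.00	0	0
VAL	O	O	1.40	+0.00	0.120	1.70	0	1
VAL	OXT	O	1.40	+0.00	0.120	1.70	0	1
VAL	CB	C	1.87	+0.00	0.110	2.00	0	0
VAL	CG1	C	1.87	+0.00	0.110	2.00	0	0
VAL	CG2	C	1.87	+0.00	0.110	2.00	0	0
*	C	C	1.87	+0.00	0.110	2.00	0	0
*	N	N	1.65	+0.00	0.170	1.85	0	0
*	O	O	1.40	+0.00	0.120	1.70	0	1
*	S	S	1.85	+0.00	0.450	2.00	0	0
*	H	H	1.00	+0.00	0.030	0.80	0	0
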