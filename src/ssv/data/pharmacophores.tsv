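# res_name	atom_name	classes (res_name '*' rows are element fallbacks)
ALA	N	donor
ALA	CA	hydrophobic
ALA	C	hydrophobic
ALA	O	acceptor
ALA	CB	hydrophobic
ALA	OXT	negative,acceptor
ARG	N	donor
ARG	CA	hydrophobic
ARG	C	hydrophobic
ARG	O	acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	hydrophobic
ARG	NE	positive,donor
ARG	CZ	hydrophobic
ARG	NH1	positive,donor
ARG	NH2	positive,donor
ARG	OXT	negative,acceptor
ASN	N	donor
ASN	CA	hydrophobic
ASN	C	hydrophobic
ASN	O	acceptor
ASN	CB	hydrophobic
ASN	CG	hydrophobic
ASN	OD1	acceptor
ASN	ND2	donor
ASN	OXT	negative,acceptor
ASP	N	donor
ASP	CA	hydrophobic
ASP	C	hydrophobic
ASP	O	acceptor
ASP	CB	hydrophobic
ASP	CG	hydrophobic
ASP	OD1	negative,acceptor
ASP	OD2	negative,acceptor
ASP	OXT	negative,acceptor
CYS	N	donor
CYS	CA	hydrophobic
CYS	C	hydrophobic
CYS	O	acceptor
CYS	CB	hydrophobic
CYS	SG	sulfur
CYS	OXT	negative,acceptor
GLN	N	donor
GLN	CA	hydrophobic
GLN	C	hydrophobic
GLN	O	acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	hydrophobic
GLN	OE1	acceptor
GLN	NE2	donor
GLN	OXT	negative,acceptor
GLU	N	donor
GLU	CA	hydrophobic
GLU	C	hydrophobic
GLU	O	acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	hydrophobic
GLU	OE1	negative,acceptor
GLU	OE2	negative,acceptor
GLU	OXT	negative,acceptor
GLY	N	donor
GLY	CA	hydrophobic
GLY	C	hydrophobic
GLY	O	acceptor
GLY	OXT	negative,acceptor
HIS	N	donor
HIS	CA	hydrophobic
HIS	C	hydrophobic
HIS	O	acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	positive,acceptor,donor,aromatic
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	positive,acceptor,donor,aromatic
HIS	OXT	negative,acceptor
ILE	N	donor
ILE	CA	hydrophobic
ILE	C	hydrophobic
ILE	O	acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
ILE	OXT	negative,acceptor
LEU	N	donor
LEU	CA	hydrophobic
LEU	C	hydrophobic
LEU	O	acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LEU	OXT	negative,acceptor
LYS	N	donor
LYS	CA	hydrophobic
LYS	C	hydrophobic
LYS	O	acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	hydrophobic
LYS	NZ	positive,donor
LYS	OXT	negative,acceptor
MET	N	donor
MET	CA	hydrophobic
MET	C	hydrophobic
MET	O	acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	sulfur
MET	CE	hydrophobic
MET	OXT	negative,acceptor
PHE	N	donor
PHE	CA	hydrophobic
PHE	C	hydrophobic
PHE	O	acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic
PHE	CD1	aromatic
PHE	CD2	aromatic
PHE	CE1	aromatic
PHE	CE2	aromatic
PHE	CZ	aromatic
PHE	OXT	negative,acceptor
PRO	N	neutral
PRO	CA	hydrophobic
PRO	C	hydrophobic
PRO	O	acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	hydrophobic
PRO	OXT	negative,acceptor
SER	N	donor
SER	CA	hydrophobic
SER	C	hydrophobic
SER	O	acceptor
SER	CB	hydrophobic
SER	OG	acceptor,donor
SER	OXT	negative,acceptor
THR	N	donor
THR	CA	hydrophobic
THR	C	hydrophobic
THR	O	acceptor
THR	CB	hydrophobic
THR	OG1	acceptor,donor
THR	CG2	hydrophobic
THR	OXT	negative,acceptor
TRP	N	donor
TRP	CA	hydrophobic
TRP	C	hydrophobic
TRP	O	acceptor
TRP	CB	hydrophobic
TRP	CG	aromatic
TRP	CD1	aromatic
TRP	CD2	aromatic
TRP	NE1	donor,aromatic
TRP	CE2	aromatic
TRP	CE3	aromatic
TRP	CZ2	aromatic
TRP	CZ3	aromatic
TRP	CH2	aromatic
TRP	OXT	negative,acceptor
TYR	N	donor
TYR	CA	hydrophobic
TYR	C	hydrophobic
TYR	O	acceptor
TYR	CB	hydrophobic
TYR	CG	aromatic
TYR	CD1	aromatic
TYR	CD2	aromatic
TYR	CE1	aromatic
TYR	CE2	aromatic
TYR	CZ	aromatic
TYR	OH	acceptor,donor
TYR	OXT	negative,acceptor
VAL	N	donor
VAL	CA	hydrophobic
VAL	C	hydrophobic
VAL	O	acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
VAL	OXT	negative,acceptor
*	C	hydrophobic
*	N	donor
*	O	acceptor
*	S	sulfur
*	P	neutral
*	F	neutral
*	CL	neutral
*	BR	neutral
*	I	neutral
*	SE	sulfur
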