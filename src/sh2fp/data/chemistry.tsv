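# residue	atom	backbone(mc)/sidechain(sc)	polarity
ALA	N	mc	donor
ALA	CA	mc	other_polar
ALA	C	mc	other_polar
ALA	O	mc	acceptor
ALA	OXT	mc	acceptor
ALA	H	mc	other_polar
ALA	HA	mc	apolar
ALA	CB	sc	apolar
ARG	N	mc	donor
ARG	CA	mc	other_polar
ARG	C	mc	other_polar
ARG	O	mc	acceptor
ARG	OXT	mc	acceptor
ARG	H	mc	other_polar
ARG	HA	mc	apolar
ARG	CB	sc	apolar
ARG	CG	sc	apolar
ARG	CD	sc	other_polar
ARG	NE	sc	charged_positive
ARG	CZ	sc	other_polar
ARG	NH1	sc	charged_positive
ARG	NH2	sc	charged_positive
ASN	N	mc	donor
ASN	CA	mc	other_polar
ASN	C	mc	other_polar
ASN	O	mc	acceptor
ASN	OXT	mc	acceptor
ASN	H	mc	other_polar
ASN	HA	mc	apolar
ASN	CB	sc	apolar
ASN	CG	sc	other_polar
ASN	OD1	sc	acceptor
ASN	ND2	sc	donor
ASP	N	mc	donor
ASP	CA	mc	other_polar
ASP	C	mc	other_polar
ASP	O	mc	acceptor
ASP	OXT	mc	acceptor
ASP	H	mc	other_polar
ASP	HA	mc	apolar
ASP	CB	sc	apolar
ASP	CG	sc	other_polar
ASP	OD1	sc	charged_negative
ASP	OD2	sc	charged_negative
CYS	N	mc	donor
CYS	CA	mc	other_polar
CYS	C	mc	other_polar
CYS	O	mc	acceptor
CYS	OXT	mc	acceptor
CYS	H	mc	other_polar
CYS	HA	mc	apolar
CYS	CB	sc	apolar
CYS	SG	sc	apolar
GLN	N	mc	donor
GLN	CA	mc	other_polar
GLN	C	mc	other_polar
GLN	O	mc	acceptor
GLN	OXT	mc	acceptor
GLN	H	mc	other_polar
GLN	HA	mc	apolar
GLN	CB	sc	apolar
GLN	CG	sc	apolar
GLN	CD	sc	other_polar
GLN	OE1	sc	acceptor
GLN	NE2	sc	donor
GLU	N	mc	donor
GLU	CA	mc	other_polar
GLU	C	mc	other_polar
GLU	O	mc	acceptor
GLU	OXT	mc	acceptor
GLU	H	mc	other_polar
GLU	HA	mc	apolar
GLU	CB	sc	apolar
GLU	CG	sc	apolar
GLU	CD	sc	other_polar
GLU	OE1	sc	charged_negative
GLU	OE2	sc	charged_negative
GLY	N	mc	donor
GLY	CA	mc	other_polar
GLY	C	mc	other_polar
GLY	O	mc	acceptor
GLY	OXT	mc	acceptor
GLY	H	mc	other_polar
GLY	HA2	mc	apolar
GLY	HA3	mc	apolar
HIS	N	mc	donor
HIS	CA	mc	other_polar
HIS	C	mc	other_polar
HIS	O	mc	acceptor
HIS	OXT	mc	acceptor
HIS	H	mc	other_polar
HIS	HA	mc	apolar
HIS	CB	sc	apolar
HIS	CG	sc	apolar
HIS	ND1	sc	donor_and_acceptor
HIS	CD2	sc	apolar
HIS	CE1	sc	apolar
HIS	NE2	sc	donor_and_acceptor
ILE	N	mc	donor
ILE	CA	mc	other_polar
ILE	C	mc	other_polar
ILE	O	mc	acceptor
ILE	OXT	mc	acceptor
ILE	H	mc	other_polar
ILE	HA	mc	apolar
ILE	CB	sc	apolar
ILE	CG1	sc	apolar
ILE	CG2	sc	apolar
ILE	CD1	sc	apolar
LEU	N	mc	donor
LEU	CA	mc	other_polar
LEU	C	mc	other_polar
LEU	O	mc	acceptor
LEU	OXT	mc	acceptor
LEU	H	mc	other_polar
LEU	HA	mc	apolar
LEU	CB	sc	apolar
LEU	CG	sc	apolar
LEU	CD1	sc	apolar
LEU	CD2	sc	apolar
LYS	N	mc	donor
LYS	CA	mc	other_polar
LYS	C	mc	other_polar
LYS	O	mc	acceptor
LYS	OXT	mc	acceptor
LYS	H	mc	other_polar
LYS	HA	mc	apolar
LYS	CB	sc	apolar
LYS	CG	sc	apolar
LYS	CD	sc	apolar
LYS	CE	sc	other_polar
LYS	NZ	sc	charged_positive
MET	N	mc	donor
MET	CA	mc	other_polar
MET	C	mc	other_polar
MET	O	mc	acceptor
MET	OXT	mc	acceptor
MET	H	mc	other_polar
MET	HA	mc	apolar
MET	CB	sc	apolar
MET	CG	sc	apolar
MET	SD	sc	apolar
MET	CE	sc	apolar
PHE	N	mc	donor
PHE	CA	mc	other_polar
PHE	C	mc	other_polar
PHE	O	mc	acceptor
PHE	OXT	mc	acceptor
PHE	H	mc	other_polar
PHE	HA	mc	apolar
PHE	CB	sc	apolar
PHE	CG	sc	apolar
PHE	CD1	sc	apolar
PHE	CD2	sc	apolar
PHE	CE1	sc	apolar
PHE	CE2	sc	apolar
PHE	CZ	sc	apolar
PRO	N	mc	other_polar
PRO	CA	mc	other_polar
PRO	C	mc	other_polar
PRO	O	mc	acceptor
PRO	OXT	mc	acceptor
PRO	HA	mc	apolar
PRO	CB	sc	apolar
PRO	CG	sc	apolar
PRO	CD	sc	other_polar
SER	N	mc	donor
SER	CA	mc	other_polar
SER	C	mc	other_polar
SER	O	mc	acceptor
SER	OXT	mc	acceptor
SER	H	mc	other_polar
SER	HA	mc	apolar
SER	CB	sc	other_polar
SER	OG	sc	donor_and_acceptor
THR	N	mc	donor
THR	CA	mc	other_polar
THR	C	mc	other_polar
THR	O	mc	acceptor
THR	OXT	mc	acceptor
THR	H	mc	other_polar
THR	HA	mc	apolar
THR	CB	sc	other_polar
THR	OG1	sc	donor_and_acceptor
THR	CG2	sc	apolar
TRP	N	mc	donor
TRP	CA	mc	other_polar
TRP	C	mc	other_polar
TRP	O	mc	acceptor
TRP	OXT	mc	acceptor
TRP	H	mc	other_polar
TRP	HA	mc	apolar
TRP	CB	sc	apolar
TRP	CG	sc	apolar
TRP	CD1	sc	apolar
TRP	CD2	sc	apolar
TRP	NE1	sc	donor
TRP	CE2	sc	apolar
TRP	CE3	sc	apolar
TRP	CZ2	sc	apolar
TRP	CZ3	sc	apolar
TRP	CH2	sc	apolar
TYR	N	mc	donor
TYR	CA	mc	other_polar
TYR	C	mc	other_polar
TYR	O	mc	acceptor
TYR	OXT	mc	acceptor
TYR	H	mc	other_polar
TYR	HA	mc	apolar
TYR	CB	sc	apolar
TYR	CG	sc	apolar
TYR	CD1	sc	apolar
TYR	CD2	sc	apolar
TYR	CE1	sc	apolar
TYR	CE2	sc	apolar
TYR	CZ	sc	apolar
TYR	OH	sc	donor_and_acceptor
VAL	N	mc	donor
VAL	CA	mc	other_polar
VAL	C	mc	other_polar
VAL	O	mc	acceptor
VAL	OXT	mc	acceptor
VAL	H	mc	other_polar
VAL	HA	mc	apolar
VAL	CB	sc	apolar
VAL	CG1	sc	apolar
VAL	CG2	sc	apolar
PTR	N	mc	donor
PTR	CA	mc	other_polar
PTR	C	mc	other_polar
PTR	O	mc	acceptor
PTR	OXT	mc	acceptor
PTR	H	mc	other_polar
PTR	HA	mc	apolar
PTR	CB	sc	apolar
PTR	CG	sc	apolar
PTR	CD1	sc	apolar
PTR	CD2	sc	apolar
PTR	CE1	sc	apolar
PTR	CE2	sc	apolar
PTR	CZ	sc	apolar
PTR	OH	sc	charged_negative
PTR	P	sc	other_polar
PTR	O1P	sc	charged_negative
PTR	O2P	sc	charged_negative
PTR	O3P	sc	charged_negative
PTR	OP1	sc	charged_negative
PTR	OP2	sc	charged_negative
PTR	OP3	sc	charged_negative
ACE	CH3	mc	apolar
ACE	C	mc	other_polar
ACE	O	mc	acceptor
NME	N	mc	donor
NME	CH3	mc	apolar
NME	CA	mc	apolar
NME	H	mc	other_polar
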