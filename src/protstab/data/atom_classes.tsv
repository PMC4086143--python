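residue	atom	classes
A	N	hydrogen_donor
A	CA	hydrophobic
A	C	hydrophobic
A	O	hydrogen_acceptor
A	CB	hydrophobic
C	N	hydrogen_donor
C	CA	hydrophobic
C	C	hydrophobic
C	O	hydrogen_acceptor
C	CB	hydrophobic
C	SG	sulphur
D	N	hydrogen_donor
D	CA	hydrophobic
D	C	hydrophobic
D	O	hydrogen_acceptor
D	CB	hydrophobic
D	CG	neutral
D	OD1	negative,hydrogen_acceptor
D	OD2	negative,hydrogen_acceptor
E	N	hydrogen_donor
E	CA	hydrophobic
E	C	hydrophobic
E	O	hydrogen_acceptor
E	CB	hydrophobic
E	CG	hydrophobic
E	CD	neutral
E	OE1	negative,hydrogen_acceptor
E	OE2	negative,hydrogen_acceptor
F	N	hydrogen_donor
F	CA	hydrophobic
F	C	hydrophobic
F	O	hydrogen_acceptor
F	CB	hydrophobic
F	CG	aromatic,hydrophobic
F	CD1	aromatic,hydrophobic
F	CD2	aromatic,hydrophobic
F	CE1	aromatic,hydrophobic
F	CE2	aromatic,hydrophobic
F	CZ	aromatic,hydrophobic
G	N	hydrogen_donor
G	CA	hydrophobic
G	C	hydrophobic
G	O	hydrogen_acceptor
H	N	hydrogen_donor
H	CA	hydrophobic
H	C	hydrophobic
H	O	hydrogen_acceptor
H	CB	hydrophobic
H	CG	aromatic,hydrophobic
H	ND1	aromatic,positive,hydrogen_donor
H	CD2	aromatic,hydrophobic
H	CE1	aromatic,hydrophobic
H	NE2	aromatic,positive,hydrogen_donor
I	N	hydrogen_donor
I	CA	hydrophobic
I	C	hydrophobic
I	O	hydrogen_acceptor
I	CB	hydrophobic
I	CG1	hydrophobic
I	CG2	hydrophobic
I	CD1	hydrophobic
K	N	hydrogen_donor
K	CA	hydrophobic
K	C	hydrophobic
K	O	hydrogen_acceptor
K	CB	hydrophobic
K	CG	hydrophobic
K	CD	hydrophobic
K	CE	neutral
K	NZ	positive,hydrogen_donor
L	N	hydrogen_donor
L	CA	hydrophobic
L	C	hydrophobic
L	O	hydrogen_acceptor
L	CB	hydrophobic
L	CG	hydrophobic
L	CD1	hydrophobic
L	CD2	hydrophobic
M	N	hydrogen_donor
M	CA	hydrophobic
M	C	hydrophobic
M	O	hydrogen_acceptor
M	CB	hydrophobic
M	CG	hydrophobic
M	SD	sulphur
M	CE	hydrophobic
N	N	hydrogen_donor
N	CA	hydrophobic
N	C	hydrophobic
N	O	hydrogen_acceptor
N	CB	hydrophobic
N	CG	neutral
N	OD1	hydrogen_acceptor
N	ND2	hydrogen_donor
P	N	neutral
P	CA	hydrophobic
P	C	hydrophobic
P	O	hydrogen_acceptor
P	CB	hydrophobic
P	CG	hydrophobic
P	CD	hydrophobic
Q	N	hydrogen_donor
Q	CA	hydrophobic
Q	C	hydrophobic
Q	O	hydrogen_acceptor
Q	CB	hydrophobic
Q	CG	hydrophobic
Q	CD	neutral
Q	OE1	hydrogen_acceptor
Q	NE2	hydrogen_donor
R	N	hydrogen_donor
R	CA	hydrophobic
R	C	hydrophobic
R	O	hydrogen_acceptor
R	CB	hydrophobic
R	CG	hydrophobic
R	CD	hydrophobic
R	NE	positive,hydrogen_donor
R	CZ	neutral
R	NH1	positive,hydrogen_donor
R	NH2	positive,hydrogen_donor
S	N	hydrogen_donor
S	CA	hydrophobic
S	C	hydrophobic
S	O	hydrogen_acceptor
S	CB	hydrophobic
S	OG	hydrogen_acceptor,hydrogen_donor
T	N	hydrogen_donor
T	CA	hydrophobic
T	C	hydrophobic
T	O	hydrogen_acceptor
T	CB	hydrophobic
T	OG1	hydrogen_acceptor,hydrogen_donor
T	CG2	hydrophobic
V	N	hydrogen_donor
V	CA	hydrophobic
V	C	hydrophobic
V	O	hydrogen_acceptor
V	CB	hydrophobic
V	CG1	hydrophobic
V	CG2	hydrophobic
W	N	hydrogen_donor
W	CA	hydrophobic
W	C	hydrophobic
W	O	hydrogen_acceptor
W	CB	hydrophobic
W	CG	aromatic,hydrophobic
W	CD1	aromatic,hydrophobic
W	CD2	aromatic,hydrophobic
W	NE1	aromatic,hydrogen_donor
W	CE2	aromatic,hydrophobic
W	CE3	aromatic,hydrophobic
W	CZ2	aromatic,hydrophobic
W	CZ3	aromatic,hydrophobic
W	CH2	aromatic,hydrophobic
Y	N	hydrogen_donor
Y	CA	hydrophobic
Y	C	hydrophobic
Y	O	hydrogen_acceptor
Y	CB	hydrophobic
Y	CG	aromatic,hydrophobic
Y	CD1	aromatic,hydrophobic
Y	CD2	aromatic,hydrophobic
Y	CE1	aromatic,hydrophobic
Y	CE2	aromatic,hydrophobic
Y	CZ	aromatic,hydrophobic
Y	OH	hydrogen_acceptor,hydrogen_donor
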