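# name	site	watson_cut	crick_cut
# Cut offsets are 0-based positions within the recognition site on the
# watson strand; overhang = crick_cut - watson_cut (>0: 5' overhang,
# <0: 3' overhang, 0: blunt).
BamHI	GGATCC	1	5
BglII	AGATCT	1	5
SalI	GTCGAC	1	5
EcoRI	GAATTC	1	5
HindIII	AAGCTT	1	5
XbaI	TCTAGA	1	5
XhoI	CTCGAG	1	5
NotI	GCGGCCGC	2	6
PstI	CTGCAG	5	1
SacI	GAGCTC	5	1
KpnI	GGTACC	5	1
ZraI	GACGTC	3	3
AjiI	CACGTC	3	3
EcoRV	GATATC	3	3
SmaI	CCCGGG	3	3
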