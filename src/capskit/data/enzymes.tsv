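name	recognition	cut_offset
ClaI	ATCGAT	2
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
XhoI	CTCGAG	1
PstI	CTGCAG	5
KpnI	GGTACC	5
SacI	GAGCTC	5
SalI	GTCGAC	1
NcoI	CCATGG	1
NdeI	CATATG	2
SpeI	ACTAGT	1
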