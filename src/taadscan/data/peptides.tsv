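# Curated peptide fixtures with their 9aaTAD core-match counts.
# expected_core_matches was computed with an independent brute-force
# constraint check and is re-verified against the scanner at load time.
# Columns: name, residues, provenance, expected_core_matches
name	residues	provenance	expected_core_matches
artificial_H41	RVWNHYRDV	cloning-artifact peptide appended in construct H41	0
artificial_H43	GIPDHYRDV	cloning-artifact peptide appended in construct H43	0
artificial_H47	PEFRRVWNHYRDV	cloning-artifact peptide appended in construct H47	0
gal80_binding_gal4	GMFNTTTMDDVYNYLFDDEDT	Gal4 854-875 Gal80-binding peptide (PDB 3E1K)	1
gal80_binding_klgal9	TQQLFNTTTMDDVYNYIFDNDE	K.l.Gal9 Gal80-binding peptide (PDB 3BTS)	1
gal4_9aatad_core	DDVYNYLFD	Gal4 9aaTAD core within the Gal80-binding region	1
klgal9_9aatad_core	DDVYNYIFD	K.l.Gal9 9aaTAD core within its Gal80-binding region	1
prjr200_junction	LLTGLFVQDWTDQ	Gal4 DBD 92-100 fused to AD-III 840-843 (constructs U39 and pRJR200#)	1
gal4_dbd_92_100	LLTGLFVQD	Gal4 DNA-binding-domain half of the artificial activation domain	0
gal4_adIII_840_843	WTDQ	AD-III half of the artificial activation domain	0
gal4_9aatad_half_867_871	YLFDD	native 9aaTAD half fused to the DBD in earlier artefacts	0
p201_hybrid	LFVQDYLLPTCIP	Gal4 DBD 96-100 fused to the P201 activator	0
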