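# Curated LexA-Gal4 reporter constructs.
# Columns:
#   name            construct identifier
#   gal4_start      1-based first Gal4 residue in the fusion, or NA
#   gal4_end        1-based last Gal4 residue, or NA
#   alt_gal4_start  alternative printed start when the source is internally inconsistent, or NA
#   alt_gal4_end    alternative printed end, or NA
#   artificial_peptide  appended cloning-artifact peptide (spaces removed), or NA
#   ha_tag          true/false
#   activity_class  strong | weak/basal | inactive | not_reported
#   note            free text (provenance, discrepancies)
name	gal4_start	gal4_end	alt_gal4_start	alt_gal4_end	artificial_peptide	ha_tag	activity_class	note
G10	1	238	NA	NA	NA	false	inactive	AD-I construct (activation domain 148-238)
G42	766	848	NA	NA	NA	false	inactive	AD-II construct
G405	840	857	NA	NA	NA	false	inactive	AD-III construct; over 100-fold weaker than the 9aaTAD constructs
G577	857	871	NA	NA	NA	false	strong	9aaTAD construct; 15 printed residues vs the 14-residue maximal-activity rule (discrepancy retained as printed)
G81	766	881	776	881	NA	false	strong	start printed as 766 and 776 in different passages; 766 canonical, alternative retained
G49	766	871	776	871	NA	false	strong	start printed as 766 and 776 in different passages; 766 canonical, alternative retained
G50	766	863	776	863	NA	false	inactive	start printed as 766 and 776 in different passages; 766 canonical, alternative retained
G44	NA	NA	NA	NA	NA	false	inactive	HA-less counterpart of H44; span not printed
G46	NA	NA	NA	NA	NA	false	inactive	HA-less counterpart of H46; span not printed
G48	NA	NA	NA	NA	NA	false	inactive	HA-less counterpart of H48; span not printed
H41	766	848	NA	NA	RVWNHYRDV	true	strong	artificial peptide from the original AD-II construct
H42	766	848	NA	NA	NA	true	weak/basal	elevated basal level, ~15% of G49
H43	766	844	NA	NA	GIPDHYRDV	true	strong	artificial peptide from the original construct
H44	766	844	NA	NA	NA	true	inactive	peptide-free counterpart of H43
H45	NA	NA	NA	NA	NA	true	not_reported	listed in the with-peptide series; span and peptide not printed
H46	NA	NA	NA	NA	NA	true	inactive	peptide-free counterpart of H45; span not printed
H47	766	823	NA	NA	PEFRRVWNHYRDV	true	strong	artificial peptide from the original construct
H48	766	823	NA	NA	NA	true	weak/basal	elevated basal level, below H42
H577	857	871	NA	NA	NA	true	strong	9aaTAD construct with an alternative fusion boundary
HaY	860	871	NA	NA	NA	true	strong	9aaTAD-only construct; the 100% normalization reference
Hdd	NA	NA	NA	NA	NA	true	inactive	LexA-HA backbone only; shows the HA tag does not activate
U39	NA	NA	NA	NA	LLTGLFVQDWTDQ	true	strong	artificial 9aaTAD from Gal4 DBD 92-100 fused to AD-III 840-843
pRJR200#	NA	NA	NA	NA	LLTGLFVQDWTDQ	true	strong	reconstruction of the original AD-III construct junction; two-fold stronger than HaY
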