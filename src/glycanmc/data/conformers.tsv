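# Glycosidic-linkage conformer table: minima locations (phi, psi in deg)
# and relative free energies (kJ/mol) of the exo-syn, anti-phi and anti-psi
# conformers as predicted by three all-atom force fields for glucan
# linkages.  is_minimum=0 marks anti-phi entries that are not true local
# minima (the values quote the lowest energy found at phi = +/-60 deg).
force_field	linkage	label	phi	psi	dE	is_minimum
CHARMM	b14	exo-syn	-74	117	0.0	1
CHARMM	b14	anti-phi	50	123	11.5	1
CHARMM	b14	anti-psi	-59	-36	7.4	1
CHARMM	a14	exo-syn	97	99	0.0	1
CHARMM	a14	anti-phi	-38	101	39.6	1
CHARMM	a14	anti-psi	87	-49	6.3	1
CHARMM	b13	exo-syn	-69	-107	0.0	1
CHARMM	b13	anti-phi	50	-110	14.3	1
CHARMM	b13	anti-psi	-84	51	9.0	1
GLYCAM	b14	exo-syn	-73	119	0.0	1
GLYCAM	b14	anti-phi	64	120	11.7	1
GLYCAM	b14	anti-psi	-74	-59	10.0	1
GLYCAM	a14	exo-syn	71	87	0.0	1
GLYCAM	a14	anti-phi	-54	101	26.9	1
GLYCAM	a14	anti-psi	76	-69	12.3	1
GLYCAM	b13	exo-syn	-76	-89	0.0	1
GLYCAM	b13	anti-phi	63	-109	13.6	1
GLYCAM	b13	anti-psi	-85	55	11.3	1
GROMOS	b14	exo-syn	-66	117	0.0	1
GROMOS	b14	anti-phi	60	119	19.6	0
GROMOS	b14	anti-psi	-70	-42	18.4	1
GROMOS	a14	exo-syn	79	89	0.0	1
GROMOS	a14	anti-phi	-60	106	28.9	0
GROMOS	a14	anti-psi	101	-49	21.5	1
GROMOS	b13	exo-syn	-63	-100	0.0	1
GROMOS	b13	anti-phi	60	-111	22.3	0
GROMOS	b13	anti-psi	-90	67	28.2	1
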