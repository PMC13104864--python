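# Curated structural-alert / reactive-group SMARTS set bundled with molfm.
# A compact default covering classic unstable, reactive, or assay-interfering
# functional groups; drop-in replacement files (e.g. the published Dundee or
# Glaxo Wellcome alert collections) can be supplied to the same loader as
# "SMARTS<whitespace>name" lines or rd_filters-style CSV.
# Format: SMARTS  name
C1OC1	epoxide
C1NC1	aziridine
C1SC1	thiirane
[#8]-[#8]	peroxide
[CX3H1]=O	aldehyde
[#6][CX3](=O)[#6]	ketone
[CX3](=O)[OX2H1]	carboxylic_acid
[CX3](=O)[OX2H0][#6]	ester
[CX3](=O)[F,Cl,Br,I]	acyl_halide
[N+](=O)[O-]	nitro
[NX2]=O	nitroso
N=[N+]=[N-]	azide
[NX2]=[NX2]	azo
[N+]#N	diazonium
[NX3][NX3]	hydrazine
[NX3][OX2H]	hydroxylamine
[SX2H]	thiol
[SX2][SX2]	disulfide
[CX3](=O)[SX2]	thioester
S(=O)(=O)[F,Cl,Br,I]	sulfonyl_halide
[CX3]=[CX3][CX3]=O	michael_acceptor
[CX4][Cl,Br,I]	alkyl_halide
N=C=O	isocyanate
N=C=S	isothiocyanate
[CX3]=[NX2]	imine
[CX3]=[CX3][OX2][#6]	enol_ether
[CX3](=O)[OX2][CX3]=O	anhydride
[NX3][CX3](=O)[OX2]	carbamate
[CX3]=[NX2][OX2H]	oxime
C#N	nitrile
[c][OX2H]	phenol
[c][OX2][CX3]=O	phenol_ester
[NX4+]	quaternary_nitrogen
[O,N,S;!R][CX4;!R][O,N,S;!R]	het_c_het_acyclic
[CX4]([OX2H])[OX2H]	geminal_diol
[CX4]([OX2H])[OX2][#6]	hemiacetal
[CX4]([OX2][#6])([OX2][#6])[#6,#1]	acetal
[c][NX3H2]	aromatic_primary_amine
[NX3][CX3](=[NX2])[NX3]	guanidine
[CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2]	aliphatic_long_chain
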