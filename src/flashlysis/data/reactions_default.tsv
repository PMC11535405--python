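# Default homogeneous water-radiolysis reaction table.
# Columns (tab-separated): kind, then kind-specific fields.
#   species <tab> name <tab> charge <tab> composition (e.g. H:2,O:1) <tab> constant_concentration_M (blank = dynamic)
#   reaction <tab> label <tab> equation ("A + B -> C + D") <tab> k <tab> unit (M-1s-1 | s-1) <tab> provenance
# Provenance tags: "core" = the peroxide/superoxide set governing the late
# H2O2 / O2- evolution under oxygenated UHDR pulses; "compilation" = standard
# room-temperature rate-constant compilation values (Buxton-style tabulation)
# standing in for the full supplementary list; "acid-base" = proton-transfer
# equilibria closing the core set thermodynamically.
species	H2O	0	H:2,O:1	55.3
species	e_aq	-1
species	OH	0	H:1,O:1
species	H	0	H:1
species	H2	0	H:2
species	H2O2	0	H:2,O:2
species	O2	0	O:2
species	O2-	-1	O:2
species	HO2	0	H:1,O:2
species	HO2-	-1	H:1,O:2
species	H3O+	1	H:3,O:1
species	OH-	-1	H:1,O:1
reaction	1a	OH + OH -> H2O2	5.50e9	M-1s-1	core
reaction	1b	OH + O2- -> O2 + OH-	1.07e10	M-1s-1	core
reaction	2a	H3O+ + O2- -> HO2 + H2O	4.78e10	M-1s-1	core
reaction	2b	HO2 + O2- -> HO2- + O2	9.70e7	M-1s-1	core
reaction	2c	H3O+ + HO2- -> H2O2 + H2O	5.00e10	M-1s-1	core
reaction	2d	HO2- + H2O -> H2O2 + OH-	1.36e6	M-1s-1	core
reaction	E1	e_aq + e_aq + H2O + H2O -> H2 + OH- + OH-	5.5e9	M-1s-1	compilation
reaction	E2	e_aq + OH -> OH-	3.0e10	M-1s-1	compilation
reaction	E3	e_aq + H + H2O -> H2 + OH-	2.5e10	M-1s-1	compilation
reaction	E4	e_aq + H3O+ -> H + H2O	2.3e10	M-1s-1	compilation
reaction	E5	e_aq + H2O2 -> OH + OH-	1.1e10	M-1s-1	compilation
reaction	E6	e_aq + O2 -> O2-	1.9e10	M-1s-1	compilation
reaction	E7	e_aq + HO2 -> HO2-	2.0e10	M-1s-1	compilation
reaction	H1	H + H -> H2	7.8e9	M-1s-1	compilation
reaction	H2	H + OH -> H2O	7.0e9	M-1s-1	compilation
reaction	H3	H + H2O2 -> OH + H2O	9.0e7	M-1s-1	compilation
reaction	H4	H + O2 -> HO2	2.1e10	M-1s-1	compilation
reaction	H5	H + HO2 -> H2O2	1.0e10	M-1s-1	compilation
reaction	H6	H + O2- -> HO2-	1.8e10	M-1s-1	compilation
reaction	H7	H + OH- -> e_aq + H2O	2.2e7	M-1s-1	compilation
reaction	O1	OH + H2 -> H + H2O	4.2e7	M-1s-1	compilation
reaction	O2	OH + H2O2 -> HO2 + H2O	2.7e7	M-1s-1	compilation
reaction	O3	OH + HO2 -> O2 + H2O	6.0e9	M-1s-1	compilation
reaction	O4	OH + HO2- -> HO2 + OH-	7.5e9	M-1s-1	compilation
reaction	P1	HO2 + HO2 -> H2O2 + O2	8.3e5	M-1s-1	compilation
reaction	A1	H3O+ + OH- -> H2O + H2O	1.4e11	M-1s-1	acid-base
reaction	A2	H2O + H2O -> H3O+ + OH-	2.53e-5	s-1	acid-base
reaction	A3	H2O2 + OH- -> HO2- + H2O	1.3e10	M-1s-1	acid-base
reaction	A4	H2O2 + H2O -> HO2- + H3O+	1.3e-1	s-1	acid-base
reaction	A5	HO2 + H2O -> O2- + H3O+	8.0e5	s-1	acid-base
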