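# SYNTHETIC stand-in primary-yield table (literature escape yields).
# G values in entities per 100 eV for low-LET electron irradiation of water
# at the ~microsecond hand-off to homogeneous kinetics.  These are standard
# compilation values, NOT scored track-structure output; secondary species
# (O2-, HO2) start at zero because they are formed only by bulk chemistry.
# Columns: species <tab> G_per_100eV <tab> note
e_aq	2.7	compilation escape yield
OH	2.8	compilation escape yield
H	0.6	compilation escape yield
H2	0.45	compilation escape yield
H2O2	0.7	compilation escape yield
H3O+	2.7	matches e_aq for electroneutrality
O2-	0.0	secondary species
HO2	0.0	secondary species
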