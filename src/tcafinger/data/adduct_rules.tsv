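name	polarity	atoms_added	atoms_removed	isotope_substitutions	charge_convention
M-H	negative			 	proton-transfer
M(C13)-H	negative			C>13C:1	proton-transfer
M+Cl	negative	Cl		 	species-attachment
M+Cl37	negative	Cl		Cl>37Cl:1	species-attachment
M+ACN-H	negative	C2H3N		 	proton-transfer
M+CH3COO	negative	C2H3O2		 	species-attachment
M+HCOO	negative	CHO2		 	species-attachment
M+Na-2H	negative	Na	H2	 	species-attachment
M+Br	negative	Br		 	species-attachment
M+Br81	negative	Br		Br>81Br:1	species-attachment
M+H	positive			 	proton-transfer
M+H2O+H	positive	H2O		 	proton-transfer
M-H2O+H	positive		H2O	 	proton-transfer
M-CO+H	positive		CO	 	proton-transfer
M-CO2+H	positive		CO2	 	proton-transfer
M-HCOOH+H	positive		CH2O2	 	proton-transfer
M-C3H4O2+H	positive		C3H4O2	 	proton-transfer
M-HCOOK+H	positive		CHO2K	 	proton-transfer
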