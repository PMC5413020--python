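name	kegg_id	formula
cis-aconitate	C00417	C6H6O6
isocitrate	C00311	C6H8O7
alpha-ketoglutarate	C00026	C5H6O5
succinate	C00042	C4H6O4
fumarate	C00122	C4H4O4
malate	C00149	C4H6O5
phosphoenolpyruvate	C00074	C3H5O6P
glutamate	C00302	C5H9NO4
hydroxybutyrate	C05984	C4H8O3
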