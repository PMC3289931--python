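gene_name	gene_symbol	direction	unique_met
Plasminogen activator, Tissue	PLAT	up	1
Plasminogen activator, Urokinase	PLAU	up	1
Interleukin 8	IL8	up	1
Chemokine (C-C motif) ligand 2	CCL2	up	0
Integrin, beta 1	ITGB1	up	0
Actin, beta	ACTB	up	0
Vinculin	VCL	up	0
Drebrin 1	DBN1	up	1
Moesin	MSN	up	1
Tissue factor pathway inhibitor 2	TFPI2	up	1
Caveolin 1	CAV1	up	0
Caveolin 2	CAV2	up	1
Tenascin-C	TNC	up	1
Transforming growth factor, beta-induced, 68 kDA	TGFBI	down	0
Serpin peptidase inhibitor, clade E, member 2	SERPINE2	down	0
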