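species	tpsa	consensus_logp	solubility_class	gi_absorption	pgp_substrate	bioavailability_score	synthetic_accessibility
genistein	90.9	2.04	moderately_soluble	high	no	0.55	2.87
hyoscyamine	49.77	2.04	soluble	high	no	0.55	4.33
01	143.83	2.64	poorly_soluble	low	no	0.55	6.14
02	143.83	2.64	poorly_soluble	low	no	0.55	6.14
03	136.76	2.85	poorly_soluble	low	yes	0.55	6.55
04	129.67	2.75	poorly_soluble	low	no	0.55	6.14
05	129.67	3.43	poorly_soluble	low	yes	0.55	6.14
06	136.76	2.63	poorly_soluble	low	yes	0.55	6.64
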