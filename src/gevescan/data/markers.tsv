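domain_accession	domain_name	marker_class	weight
PF04947	Pox_VLTF3	GEVE	required_any
PF04665	Pox_A32_ATPase	GEVE	required_any
PF03288	Pox_D5_primase	GEVE	required_any
PF04451	Capsid_NCLDV	GEVE	required_any
PF00136	DNA_pol_B	adintovirus	required_any
ADV_MCP	Adinto_major_capsid	adintovirus	required_any
ADV_mCP	Adinto_minor_capsid	adintovirus	required_any
PF05869	Dam_methyltransferase	adintovirus	supporting
PF00589	Tyrosine_recombinase	plavaka	required_any
PLV_TPASE	Plavaka_transposase	plavaka	required_any
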