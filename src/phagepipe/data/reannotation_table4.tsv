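# Curated re-annotation overlay: 24 protein families annotated "unknown
# function" in the family database, with functions proposed from structure
# comparisons and genomic context.  Products transcribed verbatim.
family_id	product	category
phrog_4858	head-tail_connector_protein	connector
phrog_12508	endopeptidase_domain-containing_protein	lysis
phrog_600	lysosyme	lysis
phrog_3838	receptor_binding_protein	tail
phrog_1030	tail_needle_knob	tail
phrog_3833	base_plate_wedge_protein	tail
phrog_2448	carbohydrate-binding_protein	tail
phrog_3018	head_decoration_protein	head and packaging
phrog_33262	phosphoadenosine_phosphosulfate_reductase	moron, auxiliary metabolic gene and host takeover
phrog_1203	phage_shock_protein_A	moron, auxiliary metabolic gene and host takeover
phrog_3614	complement_C1Q-like_protein	moron, auxiliary metabolic gene and host takeover
phrog_4435	ryanodine_receptor	moron, auxiliary metabolic gene and host takeover
phrog_4049	ABC-type_bacteriocin_transporter_peptidase_domain	moron, auxiliary metabolic gene and host takeover
phrog_11528	threonine_deaminase	moron, auxiliary metabolic gene and host takeover
phrog_2426	magnesium_chelatase	moron, auxiliary metabolic gene and host takeover
phrog_4600	DNA-binding_protein	transcription regulation
phrog_16119	transcription_initiation_factor	transcription regulation
phrog_7401	DNA-binding protein	transcription regulation
phrog_3786	transcription_initiation_factor	transcription regulation
phrog_1934	DNA-binding_protein	transcription regulation
phrog_12574	Anti-TRAP_protein	transcription regulation
phrog_6201	CI-like_repressor	transcription regulation
phrog_37032	pentapeptide_repeat_protein	other
phrog_4700	ADP-ribose_transferase	DNA, RNA, and nucleotide metabolism
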