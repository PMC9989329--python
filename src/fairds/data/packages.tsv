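id	title	source	level
migs_ba	MIGS: cultured bacteria/archaea	MIxS	sample
migs_eu	MIGS: cultured eukaryotes	MIxS	sample
mims	MIMS: metagenome/environmental	MIxS	sample
mimarks_survey	MIMARKS: survey (marker gene)	MIxS	sample
misag	MISAG: single amplified genome	MIxS	sample
mimag	MIMAG: metagenome-assembled genome	MIxS	sample
mixs_air	MIxS environmental package: air	MIxS	sample
mixs_built_environment	MIxS environmental package: built environment	MIxS	sample
mixs_host_associated	MIxS environmental package: host-associated	MIxS	sample
mixs_human_associated	MIxS environmental package: human-associated	MIxS	sample
mixs_human_gut	MIxS environmental package: human-gut	MIxS	sample
mixs_human_oral	MIxS environmental package: human-oral	MIxS	sample
mixs_human_skin	MIxS environmental package: human-skin	MIxS	sample
mixs_human_vaginal	MIxS environmental package: human-vaginal	MIxS	sample
mixs_microbial_mat_biofilm	MIxS environmental package: microbial mat/biofilm	MIxS	sample
mixs_plant_associated	MIxS environmental package: plant-associated	MIxS	sample
mixs_sediment	MIxS environmental package: sediment	MIxS	sample
mixs_soil	MIxS environmental package: soil	MIxS	sample
mixs_wastewater_sludge	MIxS environmental package: wastewater/sludge	MIxS	sample
mixs_water	MIxS environmental package: water	MIxS	sample
mixs_misc_natural_artificial	MIxS environmental package: miscellaneous natural or artificial environment	MIxS	sample
mixs_hydrocarbon_cores	MIxS environmental package: hydrocarbon resources - cores	MIxS	sample
mixs_hydrocarbon_fluids_swabs	MIxS environmental package: hydrocarbon resources - fluids/swabs	MIxS	sample
ena_default_sample	ENA default sample checklist	ENA	sample
ena_prokaryotic_pathogen	ENA prokaryotic pathogen minimal sample checklist	ENA	sample
ena_virus_pathogen	ENA virus pathogen reporting checklist	ENA	sample
ena_plant_sample	ENA plant sample checklist	ENA	sample
ena_micro_b4	ENA Micro B4 water sampling checklist	ENA	sample
ena_cheese	ENA microbial sample from cheese checklist	ENA	sample
ena_shellfish	ENA microbial sample from shellfish checklist	ENA	sample
ena_sewage	ENA sewage checklist	ENA	sample
ena_influenza_virus	ENA influenza virus reporting checklist	ENA	sample
ena_proficiency_test	ENA global microbial identifier proficiency test checklist	ENA	sample
ena_crop_plant	ENA crop plant sample checklist	ENA	sample
ena_mutagenesis	ENA mutagenesis by carcinogens checklist	ENA	sample
ena_tara_oceans	ENA Tara Oceans water sampling checklist	ENA	sample
ena_pathogen_environment	ENA pathogen-related environmental checklist	ENA	sample
ena_food_pilot	ENA food production environment pilot checklist	ENA	sample
ena_short_read_assay	ENA short-read sequencing assay	ENA	assay
ena_long_read_assay	ENA long-read sequencing assay	ENA	assay
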