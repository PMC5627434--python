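sub_site	merged_group	abbreviation	group_sample_size
Adipose - Subcutaneous	Adipose subcutaneous	ADS	380
Adipose - Visceral (Omentum)	Adipose visceral	ADV	234
Adrenal Gland	Adrenal gland	ARG	159
Artery - Aorta	Artery aorta	ATA	247
Artery - Coronary	Artery coronary	ATC	140
Artery - Tibial	Artery tibial	ATT	357
Brain - Amygdala	Brain other	BRO	779
Brain - Anterior cingulate cortex (BA24)	Brain other	BRO	779
Brain - Cortex	Brain other	BRO	779
Brain - Frontal Cortex (BA9)	Brain other	BRO	779
Brain - Hippocampus	Brain other	BRO	779
Brain - Hypothalamus	Brain other	BRO	779
Brain - Spinal cord (cervical c-1)	Brain other	BRO	779
Brain - Substantia nigra	Brain other	BRO	779
Brain - Cerebellar Hemisphere	Brain cerebellum	BRC	254
Brain - Cerebellum	Brain cerebellum	BRC	254
Brain - Caudate (basal ganglia)	Brain basal ganglia	BRB	360
Brain - Nucleus accumbens (basal ganglia)	Brain basal ganglia	BRB	360
Brain - Putamen (basal ganglia)	Brain basal ganglia	BRB	360
Breast - Mammary Tissue	Breast	BST	217
Cells - EBV-transformed lymphocytes	Lymphoblastoid cell line	LCL	132
Cells - Transformed fibroblasts	Fibroblast cell line	FIB	305
Colon - Sigmoid	Colon sigmoid	CLS	173
Colon - Transverse	Colon transverse	CLT	203
Esophagus - Gastroesophageal Junction	Gastroesophageal junction	GEJ	176
Esophagus - Mucosa	Esophagus mucosa	EMC	330
Esophagus - Muscularis	Esophagus muscularis	EMS	283
Heart - Atrial Appendage	Heart atrial appendage	HRA	217
Heart - Left Ventricle	Heart left ventricle	HRV	267
Kidney - Cortex	Kidney cortex	KDN	36
Liver	Liver	LVR	137
Lung	Lung	LNG	360
Minor Salivary Gland	Minor salivary gland	MSG	70
Muscle - Skeletal	Skeletal muscle	SMU	469
Nerve - Tibial	Tibial nerve	TNV	334
Ovary	Ovary	OVR	108
Pancreas	Pancreas	PNC	193
Pituitary	Pituitary	PIT	124
Prostate	Prostate	PRS	119
Skin - Not Sun Exposed (Suprapubic)	Skin	SKN	661
Skin - Sun Exposed (Lower leg)	Skin	SKN	661
Small Intestine - Terminal Ileum	Intestine terminal ileum	ITI	104
Spleen	Spleen	SPL	118
Stomach	Stomach	STM	204
Testis	Testis	TST	199
Thyroid	Thyroid	THY	355
Uterus	Uterus	UTR	90
Vagina	Vagina	VGN	97
Whole Blood	Whole blood	WBL	444
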