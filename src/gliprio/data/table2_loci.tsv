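ancestry_group	trait	exposure	gene_id	eqtl_tissues	n_variants	dexpr_flag	joint2df_flag
AA	HDL	current smoking	POLK	Heart Left Ventricle, Pancreas, Thyroid	5	False	False
AA	HDL	current smoking	GCNT4	Artery Aorta, Testis	4	True	False
AA	HDL	current smoking	KLK8	Skin Sun Exposed Lower leg	4	False	False
AA	HDL	current smoking	ANGPT1	Thyroid	3	False	False
AA	HDL	current smoking	CARM1	Muscle Skeletal	1	False	True
AA	HDL	current smoking	LIPC	Liver, Pancreas	1	False	False
AA	HDL	current smoking	YIPF2	Lung	1	False	True
AA	HDL	ever smoking	PTPRZ1	Artery Aorta	21	True	True
AA	HDL	ever smoking	DNAH7	Adipose Visceral Omentum, Pancreas, Thyroid	1	False	False
AA	LDL	ever smoking	CRYGN	Colon Sigmoid, Nerve Tibial	1	False	False
AA	LDL	ever smoking	FRK	Muscle Skeletal	1	False	False
AA	LDL	ever smoking	WDR86	Nerve Tibial	1	False	False
AA	TG	current drinking	BAHD1	Colon Sigmoid, Stomach, Thyroid	2	False	False
AA	TG	current drinking	DNAJC17	Esophagus Mucosa	2	False	False
AA	TG	ever smoking	TRIO	Ovary	1	False	False
AA	DBP	ever smoking	FNTB	Muscle Skeletal, Skin Sun Exposed Lower leg	3	False	False
AA	DBP	ever smoking	RAB15	Adipose Subcutaneous, Nerve Tibial, Thyroid	3	False	False
AA	MAP	current smoking	CRTAC1	Adipose Visceral Omentum, Artery Tibial	1	False	False
AA	MAP	current smoking	SULT4A1	Colon Sigmoid	1	False	False
AA	MAP	ever smoking	FNTB	Muscle Skeletal, Skin Sun Exposed Lower leg	3	False	False
AA	MAP	ever smoking	RAB15	Adipose Subcutaneous, Nerve Tibial, Thyroid	3	False	False
AA	MAP	ever smoking	KCNK13	Brain Hypothalamus	1	False	False
AA	PP	current drinking	MPI	Artery Aorta, Lung, Whole Blood	4	False	False
AA	PP	current drinking	SCAMP2	Esophagus Mucosa, Pituitary, Whole Blood	4	False	False
AA	PP	current smoking	SYN2	Artery Aorta	1	True	False
AA	PP	ever smoking	JMJD4	Nerve Tibial	2	False	False
AA	SBP	current smoking	CRTAC1	Adipose Visceral Omentum, Artery Tibial	1	False	False
AA	SBP	ever smoking	FNTB	Muscle Skeletal, Skin Sun Exposed Lower leg	2	False	False
AA	SBP	ever smoking	RAB15	Adipose Subcutaneous, Nerve Tibial, Thyroid	2	False	False
AA	SBP	ever smoking	JMJD4	Nerve Tibial	1	False	False
ASA	HDL	ever smoking	KCTD10	Artery Tibial, Skin Sun Exposed Lower leg	1	False	True
ASA	HDL	ever smoking	MYO1H	Lung	1	False	True
ASA	HDL	ever smoking	UBE3B	Colon Transverse, Skin Sun Exposed Lower leg	1	False	True
ASA	LDL	drinking habits	CPNE2	Cells Transformed fibroblasts	3	False	False
ASA	LDL	ever smoking	KANK2	Adipose Subcutaneous, Lung, Thyroid	2	False	True
ASA	TG	drinking habits	LIPC	Thyroid	1	False	True
ASA	MAP	ever smoking	ALDH2	Esophagus Mucosa, Lung, Nerve Tibial, Thyroid	2	True	True
ASA	MAP	ever smoking	TMEM116	Artery Tibial, Heart Atrial Appendage, Whole Blood	1	True	True
ASA	SBP	current smoking	ALDH2	Esophagus Mucosa, Brain Cortex, Thyroid	3	True	True
ASA	SBP	ever smoking	ALDH2	Esophagus Mucosa, Skin Sun Exposed Lower leg	1	True	True
EA	LDL	drinking habits	APOC1	Esophagus Mucosa	1	False	True
EA	TG	drinking habits	KRTCAP3	Adrenal Gland, Thyroid, Whole Blood	2	False	True
EA	TG	drinking habits	PPM1G	Adipose Subcutaneous, Stomach, Thyroid	2	False	True
HA	PP	current smoking	STIM1	Lung, Thyroid, Whole Blood	2	False	False
TRANS	LDL	ever smoking	CRYGN	Colon Sigmoid, Nerve Tibial	1	False	False
TRANS	LDL	ever smoking	WDR86	Nerve Tibial	1	False	False
TRANS	TG	drinking habits	KRTCAP3	Adrenal Gland, Thyroid, Whole Blood	1	False	True
TRANS	TG	drinking habits	PPM1G	Esophagus Muscularis, Muscle Skeletal	1	False	True
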