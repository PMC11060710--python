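cancer_site	sex	incidence_per_100k
lung	male	77.0
lung	female	55.0
colorectal	male	87.0
colorectal	female	57.0
prostate	male	174.0
prostate	female	0.0
breast	male	1.0
breast	female	166.0
melanoma	male	27.0
melanoma	female	27.0
bladder	male	27.0
bladder	female	9.0
kidney	male	21.0
kidney	female	11.0
pancreas	male	16.0
pancreas	female	13.0
stomach	male	15.0
stomach	female	7.0
esophagus	male	23.0
esophagus	female	9.0
ovary	male	0.0
ovary	female	23.0
corpus_uteri	male	0.0
corpus_uteri	female	29.0
cervix_uteri	male	0.0
cervix_uteri	female	9.0
lip_oral_pharynx	male	15.0
lip_oral_pharynx	female	7.0
thyroid	male	3.0
thyroid	female	7.0
brain_cns	male	12.0
brain_cns	female	8.0
multiple_myeloma	male	9.0
multiple_myeloma	female	6.0
hodgkin_lymphoma	male	4.0
hodgkin_lymphoma	female	3.0
lymphoid_leukemia	male	9.0
lymphoid_leukemia	female	6.0
testis	male	7.0
testis	female	0.0
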