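peptide	allele	source_loci	cohort_label
WTGTCTIGY	HLA-A*01:01	ERVFRD-1	patient
STVCNVTFTV	HLA-A*02:01	ERVFRD-1	patient
LPSNWTGTCTI	HLA-B*07:02	ERVFRD-1	patient
GPIFTNINLM	HLA-B*07:02	ERVFRD-1	patient
GPIFTNINL	HLA-B*07:02	ERVFRD-1	patient
GPVQVQVPFSM	HLA-B*07:02	ERVFRD-2	patient
RPLQRPQPG	HLA-B*08:01	ERVFRD-2	patient
YIDTWLQLMLN	HLA-A*01:01	ERVE-3	patient
SLVSKVWHKV	HLA-A*02:01	ERVE-3	patient
SIMILHRMSL	HLA-B*07:02	ERVFH21-1	patient
MILHRMSLLRL	HLA-B*08:01	ERVFH21-1	patient and healthy donor
YMRTLLDSI	HLA-A*02:01	ERVK-4;ERVK-9;ERVK-15;ERVK-16	patient
FIWQHRILL	HLA-A*02:01	ERVK-16	patient
ATCNQSLLTY	HLA-A*01:01	ERVS71-1	healthy donor
RLHQAVPLL	HLA-A*02:01	ERVS71-1	patient
FLLTSFTTGRV	HLA-A*02:01	ERVS71-1	patient
RPRVLRLISPR	HLA-B*07:02	ERVH-5	patient
ITGTWLDAIY	HLA-A*01:01	ERVK-7;ERVK-6;ERVK-21	healthy donor
GPLLSFSIL	HLA-B*07:02	ERVK-6	patient
LLIKENLFL	HLA-A*02:01	ERVK3-3	patient
YLKACLTVL	HLA-A*02:01	ERVK3-5	patient
QPQAPQQTGAF	HLA-B*07:02	ERVK-5	patient
ALMIVSMVVSL	HLA-B*08:01	ERVK-21	patient
ILVSMDRPWEA	HLA-A*02:01	ERVK-24	patient
LPATVPSLPGL	HLA-B*07:02	ERVMER61-1	patient
CLISILVSSL	HLA-A*02:01	ERVW-1	patient
MIGYFFTSCL	HLA-B*08:01	ERVW-1	healthy donor
VPHPQPPTL	HLA-B*07:02	ERVK-12	healthy donor
DLILRHHLV	HLA-B*08:01	ERVK-14;ERVK-11;ERVK-13;ERVK-3;ERVK-24;ERVK-25;ERVK-8	healthy donor
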