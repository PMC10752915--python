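sample_id	sex	age_years	histology	localization	methylation_class	classifier_score	alteration	detection_method
pLGG1	F	5	Pilocytic astrocytoma	Posterior fossa	PA_PF (V11b4)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG2	F	7	Pilocytic astrocytoma	Posterior fossa	PA_INF (V11b4)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG3	F	0	Pilocytic astrocytoma	Optic pathway	PA_MID (V11b4)	0.99	BRAF V600E-mutation	GPS; NPHD 2019 A
pLGG4	M	5	Pilocytic astrocytoma	Posterior fossa	PA_INF (V12)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG5	M	9	Pilocytic astrocytoma	Posterior fossa	PA_INF (V12)	0.94	BRAF V600E-mutation	GPS; NPHD 2019 A
pLGG6	M	14	Pilocytic astrocytoma	Midbrain	PA_INF (V12)	0.96	KIAA1549:BRAF-fusion	DNA-methylation
pLGG7	M	2	Pilocytic astrocytoma	Cerebellum	PA_PF (V11b4)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG8	F	18	Pilocytic astrocytoma	Posterior fossa	PA_PF (V11b4)	0.99	BRAF 599TT-insertion	GPS; NPHD 2019 A
pLGG9	M	3	Pilocytic astrocytoma	Posterior fossa	PA_PF (V11b4)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG10	M	8	Pilocytic astrocytoma	Parietooccipital	PA_CORT (V12)	0.97	COPC:ROS1-fusion	DNA-methylation
pLGG11	M	8	Pilocytic astrocytoma	Posterior fossa	PA_PF (V11b4)	0.81	KIAA1549:BRAF-fusion	DNA-methylation
pLGG12	F	11	Pilocytic astrocytoma	Brain stem	Not classifiable	NA	BRAF V600E-mutation	gene panel sequencing
pLGG13	M	16	Low grade glioma	Left temporal	PA_CORT (V12)	1.0	PRKAR2B:BRAF-fusion	DNA-methylation
pLGG14	F	8	Pilocytic astrocytoma	Optic pathway	PA_MID (V11b4)	0.69	KIAA1549:BRAF-fusion	DNA-methylation
pLGG15	M	1	Pilocytic astrocytoma	Brain stem	PA_INF (V12)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG16	F	5	Pilocytic astrocytoma	Posterior fossa	PA_PF (V11b4)	0.99	KIAA1549:BRAF-fusion	DNA-methylation
pLGG17	F	14	Pilocytic astrocytoma	Spinal	Not done	NA	BRAF-duplication	ddPCR
pLGG18	F	14	Pilocytic astrocytoma	Posterior fossa	PA_INF (V12)	0.86	KIAA1549:BRAF-fusion	DNA-methylation
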