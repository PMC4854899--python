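label_id	label_name	structure_id	structure_name
1	cerebral_aqueduct	1	ventricles
2	lateral_ventricles	1	ventricles
3	third_ventricle	1	ventricles
4	fourth_ventricle	1	ventricles
5	posterior_cerebral_cortex_left	2	posterior_cerebral_cortex
6	posterior_cerebral_cortex_right	2	posterior_cerebral_cortex
7	hippocampus_left	3	hippocampus
8	hippocampus_right	3	hippocampus
9	olfactory_system_left	4	olfactory_system
10	olfactory_system_right	4	olfactory_system
11	frontal_cortex_left	5	frontal_cortex
12	frontal_cortex_right	5	frontal_cortex
13	striatum_left	6	striatum
14	striatum_right	6	striatum
15	thalamus_left	7	thalamus
16	thalamus_right	7	thalamus
17	midbrain_left	8	midbrain
18	midbrain_right	8	midbrain
19	basal_ganglia_left	9	basal_ganglia
20	basal_ganglia_right	9	basal_ganglia
21	corpus_callosum_left	10	corpus_callosum
22	corpus_callosum_right	10	corpus_callosum
23	amygdala_left	11	amygdala
24	amygdala_right	11	amygdala
25	hypothalamus_left	12	hypothalamus
26	hypothalamus_right	12	hypothalamus
27	cerebellum_left	13	cerebellum
28	cerebellum_right	13	cerebellum
29	pons_left	14	pons
30	pons_right	14	pons
31	medulla_left	15	medulla
32	medulla_right	15	medulla
33	fornix_system_left	16	fornix_system
34	fornix_system_right	16	fornix_system
35	anterior_commissure	17	anterior_commissure
36	corpora_quadrigemina_left	18	corpora_quadrigemina
37	corpora_quadrigemina_right	18	corpora_quadrigemina
38	internal_capsule_left	19	internal_capsule
39	internal_capsule_right	19	internal_capsule
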