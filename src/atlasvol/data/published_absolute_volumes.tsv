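structure	dose_gy	n	mean	sem
total_brain	0.00	18	462.8	4.12
total_brain	0.10	15	455.5	4.32
total_brain	0.33	7	434.7	5.38
total_brain	0.66	11	397.1	2.51
total_brain	1.00	10	357.2	3.63
ventricles	0.00	18	18.9	0.89
ventricles	0.10	15	17.9	0.96
ventricles	0.33	7	16.6	0.75
ventricles	0.66	11	17.3	0.87
ventricles	1.00	10	21.0	1.31
posterior_cerebral_cortex	0.00	18	105.3	1.51
posterior_cerebral_cortex	0.10	15	102.1	0.9
posterior_cerebral_cortex	0.33	7	97.9	1.09
posterior_cerebral_cortex	0.66	11	85.0	1.12
posterior_cerebral_cortex	1.00	10	73.8	1.21
hippocampus	0.00	18	23.2	0.25
hippocampus	0.10	15	23.8	0.25
hippocampus	0.33	7	22.3	0.35
hippocampus	0.66	11	20.2	0.29
hippocampus	1.00	10	18.3	0.31
olfactory_system	0.00	18	48.2	0.48
olfactory_system	0.10	15	46.3	0.5
olfactory_system	0.33	7	45.5	1.02
olfactory_system	0.66	11	42.9	0.36
olfactory_system	1.00	10	39.2	0.56
frontal_cortex	0.00	18	16.7	0.28
frontal_cortex	0.10	15	16.1	0.23
frontal_cortex	0.33	7	15.6	0.26
frontal_cortex	0.66	11	13.9	0.2
frontal_cortex	1.00	10	11.4	0.19
basal_ganglia	0.00	18	9.6	0.14
basal_ganglia	0.10	15	9.4	0.14
basal_ganglia	0.33	7	9.1	0.11
basal_ganglia	0.66	11	8.5	0.06
basal_ganglia	1.00	10	7.8	0.11
striatum	0.00	18	20.9	0.23
striatum	0.10	15	20.5	0.18
striatum	0.33	7	19.9	0.34
striatum	0.66	11	17.3	0.18
striatum	1.00	10	14.3	0.22
corpus_callosum	0.00	18	10.2	0.18
corpus_callosum	0.10	15	10.3	0.14
corpus_callosum	0.33	7	9.8	0.2
corpus_callosum	0.66	11	8.9	0.11
corpus_callosum	1.00	10	7.9	0.2
amygdala	0.00	18	14.7	0.2
amygdala	0.10	15	14.3	0.13
amygdala	0.33	7	13.5	0.16
amygdala	0.66	11	12.0	0.21
amygdala	1.00	10	11.4	0.2
hypothalamus	0.00	18	8.1	0.1
hypothalamus	0.10	15	8.1	0.09
hypothalamus	0.33	7	7.8	0.08
hypothalamus	0.66	11	7.3	0.05
hypothalamus	1.00	10	6.9	0.11
thalamus	0.00	18	18.2	0.13
thalamus	0.10	15	18.0	0.22
thalamus	0.33	7	17.4	0.21
thalamus	0.66	11	16.0	0.18
thalamus	1.00	10	14.0	0.22
midbrain	0.00	18	28.7	0.32
midbrain	0.10	15	29.1	0.36
midbrain	0.33	7	27.3	0.36
midbrain	0.66	11	26.1	0.19
midbrain	1.00	10	23.5	0.26
cerebellum	0.00	18	50.4	0.7
cerebellum	0.10	15	49.8	0.5
cerebellum	0.33	7	46.0	0.59
cerebellum	0.66	11	39.8	0.36
cerebellum	1.00	10	33.7	0.31
pons	0.00	18	28.8	0.97
pons	0.10	15	29.6	0.34
pons	0.33	7	29.1	0.4
pons	0.66	11	27.4	0.15
pons	1.00	10	25.3	0.27
medulla	0.00	18	24.8	0.45
medulla	0.10	15	24.4	0.51
medulla	0.33	7	22.8	0.48
medulla	0.66	11	21.8	0.36
medulla	1.00	10	19.9	0.41
fornix_system	0.00	18	5.0	0.12
fornix_system	0.10	15	5.0	0.13
fornix_system	0.33	7	4.8	0.1
fornix_system	0.66	11	4.8	0.06
fornix_system	1.00	10	4.2	0.18
anterior_commissure	0.00	18	3.4	0.05
anterior_commissure	0.10	15	3.2	0.05
anterior_commissure	0.33	7	3.2	0.06
anterior_commissure	0.66	11	3.0	0.04
anterior_commissure	1.00	10	2.6	0.05
corpora_quadrigemina	0.00	18	15.7	0.23
corpora_quadrigemina	0.10	15	15.6	0.18
corpora_quadrigemina	0.33	7	14.8	0.32
corpora_quadrigemina	0.66	11	14.0	0.13
corpora_quadrigemina	1.00	10	12.2	0.25
internal_capsule	0.00	18	5.1	0.14
internal_capsule	0.10	15	5.3	0.07
internal_capsule	0.33	7	4.8	0.13
internal_capsule	0.66	11	4.5	0.07
internal_capsule	1.00	10	4.2	0.11
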