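structure	dose_gy	n	mean	sem
ventricles	0.00	18	4.1	0.18
ventricles	0.10	15	3.9	0.2
ventricles	0.33	7	3.8	0.15
ventricles	0.66	11	4.4	0.22
ventricles	1.00	10	5.9	0.34
posterior_cerebral_cortex	0.00	18	22.8	0.23
posterior_cerebral_cortex	0.10	15	22.4	0.1
posterior_cerebral_cortex	0.33	7	22.5	0.13
posterior_cerebral_cortex	0.66	11	21.4	0.16
posterior_cerebral_cortex	1.00	10	20.7	0.16
hippocampus	0.00	18	5.0	0.05
hippocampus	0.10	15	5.2	0.04
hippocampus	0.33	7	5.1	0.07
hippocampus	0.66	11	5.1	0.05
hippocampus	1.00	10	5.1	0.07
olfactory_system	0.00	18	10.4	0.08
olfactory_system	0.10	15	10.2	0.06
olfactory_system	0.33	7	10.5	0.16
olfactory_system	0.66	11	10.8	0.08
olfactory_system	1.00	10	11.0	0.16
frontal_cortex	0.00	18	3.6	0.05
frontal_cortex	0.10	15	3.5	0.04
frontal_cortex	0.33	7	3.6	0.04
frontal_cortex	0.66	11	3.5	0.05
frontal_cortex	1.00	10	3.2	0.04
basal_ganglia	0.00	18	2.1	0.024
basal_ganglia	0.10	15	2.1	0.017
basal_ganglia	0.33	7	2.1	0.015
basal_ganglia	0.66	11	2.2	0.019
basal_ganglia	1.00	10	2.2	0.029
striatum	0.00	18	4.5	0.05
striatum	0.10	15	4.5	0.03
striatum	0.33	7	4.6	0.05
striatum	0.66	11	4.4	0.03
striatum	1.00	10	4.0	0.03
corpus_callosum	0.00	18	2.2	0.03
corpus_callosum	0.10	15	2.3	0.021
corpus_callosum	0.33	7	2.2	0.03
corpus_callosum	0.66	11	2.2	0.022
corpus_callosum	1.00	10	2.2	0.04
amygdala	0.00	18	3.2	0.04
amygdala	0.10	15	3.1	0.03
amygdala	0.33	7	3.1	0.04
amygdala	0.66	11	3.0	0.05
amygdala	1.00	10	3.2	0.04
hypothalamus	0.00	18	1.8	0.016
hypothalamus	0.10	15	1.8	0.012
hypothalamus	0.33	7	1.8	0.015
hypothalamus	0.66	11	1.8	0.016
hypothalamus	1.00	10	1.9	0.023
thalamus	0.00	18	3.9	0.024
thalamus	0.10	15	4.0	0.021
thalamus	0.33	7	4.0	0.016
thalamus	0.66	11	4.0	0.027
thalamus	1.00	10	3.9	0.05
midbrain	0.00	18	6.2	0.05
midbrain	0.10	15	6.4	0.05
midbrain	0.33	7	6.3	0.03
midbrain	0.66	11	6.6	0.05
midbrain	1.00	10	6.6	0.09
cerebellum	0.00	18	10.9	0.09
cerebellum	0.10	15	10.9	0.04
cerebellum	0.33	7	10.6	0.07
cerebellum	0.66	11	10.0	0.07
cerebellum	1.00	10	9.4	0.04
pons	0.00	18	6.2	0.2
pons	0.10	15	6.5	0.04
pons	0.33	7	6.7	0.05
pons	0.66	11	6.9	0.05
pons	1.00	10	7.1	0.09
medulla	0.00	18	5.4	0.08
medulla	0.10	15	5.4	0.09
medulla	0.33	7	5.2	0.09
medulla	0.66	11	5.5	0.08
medulla	1.00	10	5.6	0.11
fornix_system	0.00	18	1.1	0.025
fornix_system	0.10	15	1.1	0.026
fornix_system	0.33	7	1.1	0.017
fornix_system	0.66	11	1.2	0.014
fornix_system	1.00	10	1.2	0.05
anterior_commissure	0.00	18	0.7	0.009
anterior_commissure	0.10	15	0.7	0.01
anterior_commissure	0.33	7	0.7	0.009
anterior_commissure	0.66	11	0.8	0.008
anterior_commissure	1.00	10	0.7	0.012
corpora_quadrigemina	0.00	18	3.4	0.04
corpora_quadrigemina	0.10	15	3.4	0.02
corpora_quadrigemina	0.33	7	3.4	0.04
corpora_quadrigemina	0.66	11	3.5	0.04
corpora_quadrigemina	1.00	10	3.4	0.07
internal_capsule	0.00	18	1.1	0.03
internal_capsule	0.10	15	1.2	0.013
internal_capsule	0.33	7	1.1	0.028
internal_capsule	0.66	11	1.1	0.016
internal_capsule	1.00	10	1.2	0.025
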