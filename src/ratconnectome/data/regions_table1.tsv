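region_name	hemisphere	structural_index	functional_index	tissue_class	volume_mm3
Accumbens	right	1	1	GM	8.31
Amygdala	right	2	2	GM	7.68
Anterior commissure and bed nucleus	right	3		WM	11.42
Caudate putamen and globus pallidus	right	4	3	GM	7.27
Corpus callosum	right	5		WM	31.35
Auditory cortex	right	6	4	GM	13.28
Cingulate cortex	right	7	5	GM	36.78
Entorhinal cortex	right	8	6	GM	16.72
Frontal association cortex	right	9	7	GM	19.68
Insular cortex	right	10	8	GM	44.33
Medial prefrontal cortex	right	11	9	GM	20.53
Motor cortex	right	12	10	GM	11.38
Orbitofrontal cortex	right	13	11	GM	30.83
Parietal association and somatosensory cortex	right	14	12	GM	4.17
Piriform cortex	right	15	13	GM	25.11
Retrosplenial cortex	right	16	14	GM	14.11
Temporal association cortex	right	17	15	GM	24.24
Visual cortex	right	18	16	GM	36.78
Septum and diagonal band	right	19	17	GM	41.16
Hippocampus anterodorsal	right	20	18	GM	28.71
Hippocampus posterior	right	21	19	GM	35.36
Hippocampus subiculum	right	22	20	GM	32.36
Hippocampus ventral and hypothalamus lateral	right	23	21	mixed	7.65
Hypothalamus medial and ventral tegmental area	right	24	22	GM	32.38
Internal capsule	right	25		WM	22.57
Interstitial nucleus of the posterior limb of the anterior commissure, olfactory nuclei, substantia innominata, and ventral pallidum	right	26	23	mixed	31.05
Medial geniculate	right	27		WM	7.36
Mesencephalic region	right	28		WM	22.93
Olfactory tubercle	right	29	24	GM	5.76
Periaqueductal gray	right	30		WM	15.87
Pons	right	31		WM	15.71
Raphe	right	32		WM	23.31
Substantia nigra	right	33		WM	17.82
Superior colliculus	right	34	25	GM	15.34
Thalamus dorsolateral	right	35	26	GM	26.3
Thalamus midline dorsal and ventromedial	right	36	27	GM	5.67
Zona incerta	right	37		WM	21.14
Fimbria	right	38		WM	12.66
Accumbens	left	39	28	GM	7.81
Amygdala	left	40	29	GM	7.25
Anterior commissure and bed nucleus	left	41		WM	11.09
Caudate putamen and globus pallidus	left	42	30	GM	6.77
Corpus callosum	left	43		WM	32.1
Auditory cortex	left	44	31	GM	13.99
Cingulate cortex	left	45	32	GM	36.75
Entorhinal cortex	left	46	33	GM	16.92
Frontal association cortex	left	47	34	GM	20.38
Insular cortex	left	48	35	GM	44.92
Medial prefrontal cortex	left	49	36	GM	21.91
Motor cortex	left	50	37	GM	11.99
Orbitofrontal cortex	left	51	38	GM	29.69
Parietal association and somatosensory cortex	left	52	39	GM	4.35
Piriform cortex	left	53	40	GM	23.84
Retrosplenial cortex	left	54	41	GM	13.33
Temporal association cortex	left	55	42	GM	23.01
Visual cortex	left	56	43	GM	35.83
Septum and diagonal band	left	57	44	GM	39.87
Hippocampus anterodorsal	left	58	45	GM	27.18
Hippocampus posterior	left	59	46	GM	33.6
Hippocampus subiculum	left	60	47	GM	34.85
Hippocampus ventral and hypothalamus lateral	left	61	48	mixed	8.22
Hypothalamus medial and ventral tegmental area	left	62	49	GM	31.67
Internal capsule	left	63		WM	24.38
Interstitial nucleus of the posterior limb of the anterior commissure, olfactory nuclei, substantia innominata, and ventral pallidum	left	64	50	mixed	30.19
Medial geniculate	left	65		WM	7.32
Mesencephalic region	left	66		WM	22.79
Olfactory tubercle	left	67	51	GM	5.81
Periaqueductal gray	left	68		WM	16.62
Pons	left	69		WM	16.09
Raphe	left	70		WM	22.79
Substantia nigra	left	71		WM	18.42
Superior colliculus	left	72	52	GM	14.78
Thalamus dorsolateral	left	73	53	GM	27.57
Thalamus midline dorsal and ventromedial	left	74	54	GM	6.02
Zona incerta	left	75		WM	22.44
Fimbria	left	76		WM	11.89
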