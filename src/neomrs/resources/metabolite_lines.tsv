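# Simplified 1H line lists for brain metabolites (singlet/multiplet centroids,
# relative proton amplitudes), compiled from standard brain-metabolite
# literature values. One row per resonance: metabolite <TAB> ppm <TAB> protons.
# J-coupling evolution at short TE is approximated by static line positions.
metabolite	ppm	protons
ascorbate	3.73	1
ascorbate	4.01	1
lactate	1.31	3
lactate	4.10	1
myo_inositol	3.27	1
myo_inositol	3.52	4
myo_inositol	3.61	1
phosphorylethanolamine	3.22	2
phosphorylethanolamine	3.98	2
creatine	3.027	3
creatine	3.913	2
phosphocreatine	3.029	3
phosphocreatine	3.930	2
glutamine	2.11	2
glutamine	2.44	2
glutamine	3.75	1
glutamate	2.05	2
glutamate	2.34	2
glutamate	3.74	1
glutathione	2.15	2
glutathione	2.55	2
glutathione	2.95	2
glutathione	3.77	2
glycine	3.547	2
taurine	3.25	2
taurine	3.42	2
gpc	3.212	9
gpc	3.66	2
gpc	3.90	1
pcho	3.208	9
pcho	3.58	2
pcho	4.24	1
phenylalanine	3.11	1
phenylalanine	3.27	1
phenylalanine	3.98	1
gaba	1.89	2
gaba	2.28	2
gaba	3.01	2
aspartate	2.65	1
aspartate	2.80	1
aspartate	3.89	1
naa	2.008	3
naa	2.49	1
naa	2.67	1
naa	4.38	1
naag	2.042	3
naag	2.19	2
naag	4.13	1
acetate	1.90	3
alanine	1.47	3
alanine	3.77	1
beta_hydroxybutyrate	1.19	3
beta_hydroxybutyrate	2.31	1
beta_hydroxybutyrate	2.41	1
beta_hydroxybutyrate	4.15	1
valine	0.98	3
valine	1.03	3
valine	2.26	1
valine	3.60	1
glucose	3.23	1
glucose	3.40	1
glucose	3.53	1
glucose	3.72	1
glucose	3.84	1
scyllo_inositol	3.34	6
threonine	1.32	3
threonine	3.58	1
threonine	4.25	1
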