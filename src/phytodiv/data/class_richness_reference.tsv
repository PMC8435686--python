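chemical_class	total_richness	fruit_specific_richness	leaf_specific_richness
Benzene and substituted derivatives	75	5	0
Carboxylic acids and derivatives	122	25	1
Flavonoids	104	3	0
Organo-oxygen compounds	65	5	0
Other	37	4	0
Prenol lipids	124	6	0
Unknown	179	14	1
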