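# Demo pathway collection (synthetic curation for testing/examples; not a KEGG export).
gly_ser_thr	Glycine, serine and threonine metabolism	Glycine	Serine	Threonine	Sarcosine	Betaine	Creatine	N,N-Dimethylglycine	Hydroxypyruvate	Choline
ala_asp_glu	Alanine, aspartate and glutamate metabolism	Alanine	Glutamine	N-Acetylaspartate	N-Acetylglutamate	Succinate	Fumarate	Pyruvate	alpha-Ketoglutarate
phe_metabolism	Phenylalanine metabolism	Phenylalanine	Phenylacetylglycine	Hippurate	Benzoate	Tyrosine	ortho-Hydroxyphenylacetate
glyoxylate_dicarboxylate	Glyoxylate and dicarboxylate metabolism	Glycine	Formate	Citrate	cis-Aconitate	Hydroxypyruvate	Malate	Glutamine	Serine
ketone_bodies	Synthesis and degradation of ketone bodies	Acetoacetate	3-Hydroxybutyrate	Acetone
tca_cycle	Citrate cycle (TCA cycle)	Citrate	cis-Aconitate	Succinate	Fumarate	Malate	alpha-Ketoglutarate	Pyruvate
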