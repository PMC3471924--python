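gene_function	overlap	list_size
tgfb_responsive	144	313
mg_development	89	313
breast_cancer_associated	41	313
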