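module	gene
neural_progenitor	SOX2
neural_progenitor	NES
neural_progenitor	SOX21
neural_progenitor	VIM
neural_progenitor	TUBB2B
neuron	ELAVL3
neuron	STMN2
neuron	MAP2
neuron	TUBB2B
neural_crest	SOX10
neural_crest	SIX1
neural_crest	PRPH
neural_crest	NEUROG1
neural_crest	NEUROG2
neural_crest	NEUROD1
mesoderm	MEOX1
mesoderm	TCF15
mesoderm	PAX1
mesoderm	TWIST1
mesoderm	FOXC2
mesoderm	MYF5
blood	HBZ
blood	HBG1
blood	GYPA
blood	KLF1
blood	GATA1
blood	SPI1
skin	KRT5
skin	KRT8
skin	KRT14
skin	KRT18
skin	KRT15
skin	TP63
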