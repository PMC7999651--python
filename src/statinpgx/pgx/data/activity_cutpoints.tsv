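# schema_version: 1
# Activity-score -> phenotype cutpoints for activity_score genes.
# Intervals are half-open: score_min <= score < score_max, so the rows of a
# gene tile the whole score axis (copy-number scaling can land between the
# canonical diplotype scores).
gene	score_min	score_max	phenotype
CYP2D6	0	0.001	PM
CYP2D6	0.001	1.25	IM
CYP2D6	1.25	2.5	NM
CYP2D6	2.5	999	UM
CYP2C9	0	0.75	PM
CYP2C9	0.75	1.75	IM
CYP2C9	1.75	999	NM
CYP1A2	0	1.75	slow
CYP1A2	1.75	2.375	normal
CYP1A2	2.375	999	rapid
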