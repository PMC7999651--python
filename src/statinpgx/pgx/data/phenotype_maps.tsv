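# schema_version: 1
# Diplotype -> phenotype lookup for diplotype_map genes.  Diplotypes are
# unordered; keys are stored reference-allele-first.  Vocabularies:
#   SLCO1B1: NF (normal), DF (decreased), PF (poor transporter function)
#   CYP3A5:  NM/IM (expressers, >=1 *1) and PM (non-expresser)
#   CYP2C19 / CYP2B6: PM/IM/NM/RM/UM metabolizer labels
gene	diplotype	phenotype
SLCO1B1	*1/*1	NF
SLCO1B1	*1/*1B	NF
SLCO1B1	*1B/*1B	NF
SLCO1B1	*1/*5	DF
SLCO1B1	*1B/*5	DF
SLCO1B1	*5/*5	PF
CYP3A5	*1/*1	NM
CYP3A5	*1/*3	IM
CYP3A5	*1/*6	IM
CYP3A5	*3/*3	PM
CYP3A5	*3/*6	PM
CYP3A5	*6/*6	PM
CYP2C19	*1/*1	NM
CYP2C19	*1/*2	IM
CYP2C19	*2/*2	PM
CYP2C19	*1/*17	RM
CYP2C19	*2/*17	IM
CYP2C19	*17/*17	UM
CYP2B6	*1/*1	NM
CYP2B6	*1/*5	NM
CYP2B6	*5/*5	NM
CYP2B6	*1/*9	IM
CYP2B6	*5/*9	IM
CYP2B6	*9/*9	PM
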