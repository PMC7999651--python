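# schema_version: 1
# Per-gene translation rule.
#   diplotype_map    — phenotype looked up in phenotype_maps.tsv by diplotype
#   activity_score   — sum of per-allele activity values (scaled by copy
#                      number / 2 when a copy-number assay exists), then
#                      mapped through activity_cutpoints.tsv
#   transporter_merge — 0 variant alleles -> wild-type, exactly 1 ->
#                      heterozygous, >= 2 -> mutant
#   genotype_label   — the diplotype string itself is the reported level
# `default_activity` is the activity value of the reference allele.
gene	reference_allele	rule	default_activity	has_copy_number
SLCO1B1	*1	diplotype_map	.	no
CYP3A5	*1	diplotype_map	.	no
CYP2C19	*1	diplotype_map	.	no
CYP2B6	*1	diplotype_map	.	no
CYP2D6	*1	activity_score	1	yes
CYP2C9	*1	activity_score	1	no
CYP1A2	*1A	activity_score	1	no
SLC22A1	*1	transporter_merge	.	no
ABCB1	ref	transporter_merge	.	no
UGT2B7	*1	genotype_label	.	no
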