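# Headline funnel counts from the TCGA-PRAD discovery cohort analysis:
# exploratory age-associated miRNAs (FDR <= 0.10), the final filtered set,
# the subset with promoter methylation coverage, and its concordance split.
n_exploratory: 105
n_final: 65
n_integrated: 37
n_concordant: 20
n_discordant: 17
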