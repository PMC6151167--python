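# Desk-scale end-to-end smoke configuration: a synthetic three-population
# transect with two autosomes and a Z contig, analysed with the standard
# filter thresholds. Window span matches the simulated locus length and the
# jackknife block span is shrunk to the contig scale.
window_span: 20000
assume_callable: true          # the synthetic study writes a variants-only VCF
jackknife_block_span: 60000
mantel_permutations: 199
synth: {}                      # SyntheticStudySpec defaults
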