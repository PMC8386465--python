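# Study conditions for the synthetic analysis: a community emulating the
# structure of a curated rrn-copy-number collection.  Species counts, copy
# numbers (1-19), the fraction of diverged operon copies, and the number of
# deliberately shared variants are fixed here; every script reads this file.
seed: 20210721
outdir: results/run

community:
  n_species: 150
  genomes_per_species: ["geometric", 0.3]   # mean ~3.3 genomes per species
  copies_per_genome: ["uniform", 1, 19]     # cover every observed copy class
  intragenomic_subs: ["mixture", 0.5, 5]    # half the copies diverge by 5 subs
  intergenomic_subs: 2
  interspecies_subs: 100
  shared_variant_links: [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]

regions: [full-length, V3-V4, V4, V4-V5]
boundary_policy: drop
gap_policy:
  mode: gap-run-single-difference
  count_terminal_gaps: true
d_max: 0.10
# full sweep: 0.25% to 10% in 0.25-point steps
thresholds: {start: 0.0025, stop: 0.10, step: 0.0025}
confidence: 0.95
randomizations: 10
min_species_per_copy_class: 5
clusterer: opticlust
restarts: 1
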