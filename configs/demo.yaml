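# Demo pipeline configuration: a small synthetic mixed culture with
# three discrete populations of two members each, planted auxotrophies
# (vitamin B12 absent everywhere, mirroring a community that must take
# B12 from the medium), shotgun reads, and a correlated time series.
seed: 1
culture_id: demo

simulate:
  community:
    n_populations: 3
    members_per_population: 2
    genome_length: 20000
    gc: 0.5
    within_divergence: 0.01
    between_divergence: 0.10
    pathway_truth:
      pop1:
        vitamin-b12: false
        biotin: false
        thiamine: false
      pop2:
        vitamin-b12: false
        riboflavin: false
      pop3:
        vitamin-b12: false
  reads:
    n_reads: 20000
    read_length: 150
    error_rate: 0.005
  time_series:
    n_focal: 6
    n_environment: 20
    n_samples: 45
    n_blocks: 3
    block_rho: 0.8

recruit:
  kmer: 21
  major_threshold: 0.01

ani:
  threshold: 97.0
  distinct_below: 90.0

cooccur:
  n_permutations: 199
  rho_min: 0.5
  q_max: 0.05

pangenome:
  core_fraction: 1.0
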