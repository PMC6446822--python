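# Second selection experiment: release strategy (everywhere vs whack-a-mole)
# crossed with selection regime (homogeneous 12% vs heterogeneous 5/10/20%
# refuges re-randomized each generation); 150-larva bioassays.
experiment: 2
n_subpops: 3
n_replicates: 3
founder_pupae: 200
founder_r_freq: 0.075
generations: 4
bioassay_fraction: 0.10
dispersal_fraction: 0.10
release_start_generation: 1
master_seed: 42
strategy:
  base_ratio: 4.0
  whack_multiplier: 3
regime:
  homogeneous_refuge: 0.12
  heterogeneous_refuges: [0.05, 0.10, 0.20]
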