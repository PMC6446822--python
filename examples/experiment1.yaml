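# First selection experiment: three release treatments (control, everywhere
# 4:1, whack-a-mole 12:1) in 3-cage networks at a 10% refuge.
experiment: 1
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
  experiment1_refuge: 0.10
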