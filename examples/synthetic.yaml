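# Synthetic 2:2 dimer-of-dimers variant pair (wild type vs spring-perturbed mutant)
seed: 1
systems:
  - id: wt
    phenotypes: [trophic, nociception]
  - id: mut
    phenotypes: [trophic]
synthetic:
  geometry: dimer_of_dimers
  n_chains: 4
  beads_per_chain: 30
  jitter: 0.25
  remove_fraction: 0.3
  perturbation_radius: 7.0
nma:
  cutoff: 10.0
  spring_k: 1.0
  n_modes: 20
  amplitude: 1.0
  n_frames: 21
  relax: false
similarity:
  r_threshold: 0.6
  p_threshold: 0.001
  n_permutations: 9999
network:
  corr_threshold: 0.7
  dist_threshold: 10.0
  frame_fraction: 0.75
  modularity_tolerance: 0.05
  min_community_size: 10
  k_paths: 500
interactions:
  hbond_distance: 3.0
  hbond_angle: 20.0
  salt_bridge_distance: 3.2
  occupancy_threshold: 0.5
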