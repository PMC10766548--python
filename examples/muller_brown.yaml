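# Desk-scale UDD-AL campaign on the rescaled Müller–Brown landscape.
oracle:
  name: muller_brown
  scale: 0.1

init_data:
  temperature: 350.0
  dt: 0.5
  n_steps: 10000
  stride: 80        # -> 125 near-minimum seed samples
  energy_window: 10.0

training:
  initial_lr: 0.001
  batch_size: 32
  patience_epochs: 50
  annealing_factor: 0.5
  min_lr: 1.0e-5
  force_weight: 1.0
  max_epochs: 1000

ensemble:
  n_members: 8
  hidden_sizes: [32, 16, 8]

md:
  temperature: 350.0
  dt: 1.0
  friction: 0.01
  max_steps: 1500
  threshold: 0.6    # above the basin-rim rho, below the committee ceiling

bias:
  A: 37.2           # ~5x the escape barrier of the seeded basin
  B: 0.44           # ~ the median near-minimum committee spread sigma_E
  active_from_iteration: 3
  escalation_fraction: 0.7
  escalation_factor: 1.15

al:
  n_sims_per_iteration: 16
  n_iterations: 10
  seed_pool_size: 25

compare:
  scenarios:
    - {name: md_350K, temperature: 350.0, bias: false}
    - {name: udd_350K, temperature: 350.0, bias: true, active_from_iteration: 3}
    - {name: md_600K, temperature: 600.0, bias: false}
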