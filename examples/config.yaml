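# Example run configuration with every block spelled out.
# Any omitted key falls back to the documented default; unknown keys are
# rejected before any simulation starts.
seed: 42
mode: full_workspace        # reactive | single_reentrant | full_workspace
lifespan: 300

world:
  width: 15
  height: 15
  food_rate: 0.15           # Poisson arrivals per step
  food_value: 12.0          # energy units per item
  predator: true
  predator_bias: 0.3        # probability of stepping toward the nearest agent
  p_capture: 0.12
  freeze_capture_factor: 0.3
  noise_sd: 0.0
  kernel: inverse           # 1/(1+d); or "exp"

agent:
  energy_max: 100.0
  initial_energy: 60.0

evolution:
  pop_size: 50
  n_generations: 20
  lifespan: 300
  selection: tournament
  tournament_k: 3
  elitism_count: 2
  mut_rate: 0.15
  mut_sd: 0.15

metrics:
  arousal_threshold: 0.7
  entropy_window: 50
  min_bout: 20
  d_max: 5
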