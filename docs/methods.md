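# Methods

This note documents the modelling choices behind `ahasim`: what the
simulator assumes, which parameters matter, what the synthetic world does
and does not emulate, and where the design was genuinely open.

## 1. Architecture

### State variables

At each timestep an agent holds: a stimulus field `s` (seven modalities in
[0, 1]), a gated percept `ŝ`, a motivation per survival circuit
`M_c ∈ [0, 1]`, and a global organismic state (GOS) consisting of exactly
one dominant circuit, its arousal `A ∈ [0, 1]`, and the length of the
current dominance bout.  The modalities are four external cues (food,
predator, water, conspecific — distance-kernel sums over sources), two
internal ones (gut emptiness `1 − energy/energy_max`, thirst level
`1 − hydration`), and an ambiguous probe cue that is always zero in the
world and injected only by the experiment harness.  The thirst level as an
internal modality mirrors gut emptiness; it is what makes drinking a
*satisfiable* minor need, which the displacement scenario requires.

### Response functions

Perception→motivation links are Hill sigmoids
`R(x) = x^g / (x^g + h^g)` with gain `g ∈ [0.2, 4]` and half-saturation
`h ∈ (0, 1]`.  They are bounded, monotone, zero at zero, and equal ½ at
`x = h`, which makes hand-derived test oracles straightforward.  A
circuit's motivation is the weight-normalised mean of its link responses;
link weights have a floor of 10⁻³ so that no circuit can evolve an
all-zero weight set, which would leave the normalisation undefined.

### Competition, hysteresis, arousal

Dominance changes only when a challenger clears the incumbent by the
margin `θ(A) = θ_hi − (θ_hi − θ_lo)·A`.  The *direction* of the arousal
dependence was an open choice; we make θ shrink with arousal: a calm state
is sticky, an urgent genuinely-stronger need can seize control.  The
opposite convention can be tested by swapping the bounds.  Ties break by a
fixed configured priority order — reproducibility over realism.

Arousal is set to the dominant circuit's motivation at every appraisal
(the simplest reading of arousal as the strength of the dominant need) and
decays only through dissipation: once a bout exceeds the genome's
`dissipation_onset` (default range 1–60 steps), `A ← A·(1 − ρ)` per step.
Because appraisal refreshes `A` each step, dissipation does not compound
across steps; its effect is that the *post-dissipation* arousal is what the
next step's attention gate sees.  That is deliberate: dissipation works by
re-broadening attention, letting a suppressed circuit compete, not by
directly erasing the incumbent's motivation.

### Attention

Non-dominant-linked modalities are gated linearly,
`w = clamp(1 − α·A, 0, 1)`.  Linear-in-arousal suppression is the simplest
monotone gate jointly driven by state and arousal; internal modalities are
gated exactly like external ones.  Consequence (tested): two agents with
identical genomes but different current states perceive the same stimulus
field differently whenever `α·A > 0`, and their behavioural trajectories
diverge — the mechanical sense of subjectivity this model supports.

### Action selection

One-step re-entrant lookahead: the forward model maps (stimuli, action) to
predicted stimuli; the *same* attention and appraisal code then yields a
predicted arousal; the agent minimises it (maximises under a
positive-valence dominant).  Exact ties are broken uniformly at random from
the seeded stream, which is also the model's only source of spontaneity.
The reactive tier replaces all of this with a fixed reflex table on raw
stimuli (strongest of predator/food cue wins; eat when the food cue
saturates, i.e. food within reach), and the single-re-entrant tier predicts
through the dominant circuit only.

Two forward-model choices deserve emphasis:

* **Eating** is possible on food in the current *or an adjacent* cell
  (move-and-consume), and predicts a gut reduction of
  `food_value / energy_max`.
* **Approaching food** predicts the kernel-shifted (closer) food cue *and*
  an anticipated gut relief of `meal · predicted_cue`.  Without this
  anticipatory term a one-step arousal minimiser never approaches food —
  a nearer food cue only *raises* predicted hunger — and evolution
  converges on freezing in place.  The term encodes the agent's
  expectation that approaching food brings a meal into its near future; it
  also means approach decisions carry a systematic positive prediction
  error (the anticipation gap), which we consider a feature of the
  one-step horizon, not a bug.

Capture probability is *not* part of any stimulus or prediction: predation
risk shapes behaviour only through the predator cue and the fear circuit.
This is why scenario E2 can switch capture off without altering behaviour.

## 2. The world

A toroidal `15 × 15` grid (Chebyshev 8-neighbour movement), Poisson food
arrivals (default 0.15 items/step, 12 energy units each), one predator
performing a biased random walk (default bias 0.3 toward the nearest
agent; a perfectly persistent chaser makes survival impossible at equal
speeds, so pursuit is intermittent), capture attempts within distance 1 at
`p = 0.12` (× 0.3 if the prey froze), optional water, optional Gaussian
perceptual noise.  The stimulus kernel is `1/(1 + d)` (exponential decay
available in config).  Agents pay per-action energy costs (0.05 for
freezing up to 0.8 for fleeing) and die at zero energy.

What this world does **not** emulate: continuous space, multi-predator
ecology, social behaviour beyond a presence cue, diurnal or seasonal
structure, and any perception of conspecifics' states.  Passing tests
therefore show that the *architecture* produces the predicted behavioural
patterns in a minimal foraging/predation ecology — not that real animals
in rich environments would show them at the same effect sizes.

## 3. Evolution

Generational GA: fitness `w₁·survived + w₂·terminal_energy/energy_max +
w₃·offspring` with default weights (1, 1, 2); the reproduction term is
carried in the interface but zero under the default architecture (no
reproduction circuit in v1).  Tournament selection (k = 3, sampled without
replacement), uniform crossover (the two hysteresis bounds inherit jointly
so every offspring scalar is literally one parent's value while `lo ≤ hi`
is preserved), Gaussian mutation with sd scaled to each field's range,
clamping at the bounds.  By default every genome is evaluated on one and
the same world stream ("fixed evaluation seeds"): identical genomes then
score identically, which makes elitism's max-fitness guarantee exact; the
cost is adaptation to one world realisation, acceptable at smoke-test
scale.  Welfare indicators never enter the fitness.

A note on attention: because neural processing carries no explicit cost in
this model, the attention slope α earns little direct fitness benefit, and
under the GA it drifts (and narrow attention near predators can even be
selected *against*).  The scenario harness therefore evolves the
response-function parameters while pinning the modulator genes at reference
values (α = 0.8, θ = (0.02, 0.08), ρ = 0.5, onset 25) — the architecture
config supports freezing them — so that the behavioural contrasts probe one
well-defined attention regime rather than whatever regime a particular GA
run wandered into.

## 4. Welfare metrics

All metrics are pure functions of the trace.

* **Behavioural entropy**: Shannon entropy (bits) of action frequencies in
  sliding windows (default 50 steps).
* **Stress index**: `high_arousal_fraction × (1 + non_reducing_switch_rate
  per 100 steps)`, a switch being non-reducing when mean arousal in the
  k = 10 steps after it is at least the mean in the 10 steps before.  The
  composition (product with a switch-rate bonus) is one way of combining
  persistent high arousal with ineffective switching into a scalar; it is
  exposed in config so alternatives can be compared.
* **Displacement events**: a short (≤ 5 steps) alien-circuit interruption
  between two long (≥ 20 steps) bouts of one circuit whose preceding bout
  shows no net arousal reduction (tolerance 0.05, raised to 0.1 under
  stimulus noise).  Purely trace-syntactic: no appeal to intent.
* **Ambiguity bias**: `P(food-consistent | hunger-held) − P(food-consistent
  | fear-held)` over probe responses, with a seeded percentile bootstrap
  CI.  Food-consistent = {eat, approach_food}; danger-consistent =
  {flee, freeze}.

None of these claims to measure phenomenal experience; they quantify
trace-level constructs only.

## 5. Scenario experiments

Each scenario is fully determined by (spec, seed) and analysed with
rank-based statistics at the replicate level (Wilcoxon signed-rank when
arms are paired within genome, Mann-Whitney otherwise), 30 replicates by
default.

* **E1 / E4** probe held states: the same stimulus frame is presented to an
  agent whose GOS is clamped (hunger vs fear, arousal 0.8), 20 probes per
  replicate, cycling over the ten fittest genomes of the evolved
  population.  The reactive tier is run as a negative control and must show
  a null contrast.
* **E2** contrasts a world whose only food sits under a leashed predator
  with the same world plus a safe, poorer, more reliable patch; agents
  start hungry in the far corner.  Capture is disabled (it is behaviourally
  inert, see §1) so the stress readout is not confounded by trace
  truncation; stress is paired within genome.  Threshold 0.45 for "high"
  arousal reflects the realised arousal scale of evolved genomes, whose
  weight-normalised motivations rarely approach 1.
* **E3** uses a fixed, documented reference genome in which gut emptiness
  dominates hunger — so the experimental gut clamp (0.1 vs 0.9) genuinely
  sets the arousal level — with full-strength attention, high stimulus
  noise (sd 0.25) and a distant non-lethal predator as the fear-cue source.
  Readout: mean windowed entropy, low-arousal arm minus high-arousal arm.
* **E5** uses a reference genome and a two-circuit architecture (hunger
  blocked by a phantom food cue with nothing to eat; thirst satisfiable,
  water everywhere, slow rehydration debt).  With dissipation disabled the
  thirst circuit can never clear the hysteresis margin and zero
  displacement events occur; enabled, the periodic arousal decay
  re-broadens attention and short drink bouts interrupt the hunger bouts
  roughly every 90 steps.

Reference genomes are used where a prediction concerns a specific,
analytically understood parameter regime (E3, E5); evolved populations are
used where the prediction should hold for adapted agents generally (E1,
E2, E4).  Sensitivity: with freely evolved modulators or unfiltered
populations the E1–E4 effects keep their direction in most but not all GA
runs; the packaged tests fix the population seed, and the acceptance
script reports whatever the seed it is given produces.

## 6. Numerical and reproducibility choices

* All streams derive from one master seed via `SeedSequence` spawn keys
  (strings CRC-mapped to uint32), so adding consumers never perturbs
  existing streams; derived integer seeds stay below 2³¹.
* Exact float equality is used for tie detection in action selection
  (ties are then broken randomly); motivation monotonicity tolerances in
  tests are 10⁻¹².
* Traces are written with `%.10g` floats and a provenance header (config
  hash, seed, version); identical config + seed reproduces files
  bit-identically.
* Problem sizes: the packaged adaptation run uses population 50, 20
  generations, lifespan 300; scenario populations use population 24, 8
  generations, lifespan 200; property checks use 10³–10⁵ sampled frames.
  These sizes give stable readouts at desk scale while keeping a full test
  run under a minute of compute.

## 7. Known limitations

* No individual learning: the forward model and response functions are
  fixed within a lifetime (the interface leaves the hook open).
* One-step lookahead only; the anticipatory-relief term in the approach
  transition is a stand-in for the planning depth the model lacks.
* Arousal is winner-take-all; no blending or leaky integration across
  circuits (config extension point).
* Attention carries no processing cost, so its slope is weakly constrained
  by selection (see §3).
* The reactive reflex table and the action repertoire are minimal; adding
  actions changes entropy ceilings and should be accompanied by re-run
  calibration of the entropy-based scenarios.
* Behavioural non-identifiability of internal structure (an observer
  cannot reconstruct the internal model from behaviour alone) is discussed
  in the field but not formalised or tested here.
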