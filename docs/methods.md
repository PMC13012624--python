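# Methods

This note documents the model implemented in `fearcons`: its assumptions,
the parameters that matter, the numerical choices, what the synthetic
environment generator does and does not emulate, and the design decisions
taken where the architecture was genuinely open.

## Environments and sensory code

A context is a draw of 50 categorical features, 10 values each, i.i.d.
uniform. The sensory cortex (SC) represents it as a one-hot block code of
500 binary units, so the number of shared active SC bits between two
contexts equals the number of shared features exactly. Similarity-controlled
families are generated by fixing a random fraction *x* of the base context's
features and resampling the remainder uniformly; chance matches are allowed,
so the realized overlap exceeds the nominal one by `(1 − x)/10` on average.
Protocol summaries that depend on similarity therefore report the *nominal*
level while the underlying dynamics see the realized one. Recall cues are
degraded by clearing a fraction of the set bits (masking only — blurring
never introduces spurious features).

What this generator does **not** emulate: graded/continuous sensory
features, correlated feature statistics of natural environments,
interoceptive context components, or temporal context drift. Passing tests
therefore show that the circuit-level mechanisms behave as described under a
clean categorical world, not that the model quantitatively fits any
behavioural dataset.

## Regions

All regions are binary k-winner-take-all (kWTA) layers driven by fixed,
seeded SC projections; ties in kWTA break deterministically toward the
lowest unit index, and all stochasticity is injected explicitly through the
model's seeded generator.

**Hippocampus (HIP).** 500 units, k = 20 (4% active). The recurrent
projection learns with a bounded, potentiation-only Hebbian rule
(`η = 0.25`, cap `w_max = 1`), initialized with a small uniform background
(≤ 0.02) so that the encoding-strength metric (within-engram mass over total
outgoing mass) is informative. There is no LTD; weakening happens only
through per-day multiplicative decay (0.945/day, see *Calibration*). Recall
applies the cue for one step and then runs recurrent-only convergence for 30
steps with an activity floor (`θ_recall = 9.5` in units of summed drive);
decayed engrams fall below the floor and activity collapses, which is how
forgetting expresses itself. Retrieval counts as successful when the F1
overlap between the converged state and the stored engram reaches 0.9.

**Entorhinal gate.** During Perception the EC output mirrors the input;
during Recall it is driven by HIP (relative threshold: bits at ≥ 50% of the
maximum drive). An F1 score between input and output patterns decides the
recall route: hippocampal if F1 ≥ 0.85, otherwise cortical. The bar sits
above 0.8 deliberately — the renewal experiments treat 80%-overlap contexts
as *different* environments, so the recognition gate must not declare a
match there.

**Neocortex (CTX).** 500 units, k = 60 (12% — denser than HIP, so engrams of
similar contexts overlap strongly; this is the substrate of time-dependent
generalisation). Awake learning is weak (`η = 0.002`); consolidation happens
during Sleep at `η = 0.12` per co-active step when hippocampal replay
reactivates the engram. Cortical weights decay at 0.987/day (half-life ≈ 53
days). Because the dense code completes less reliably from degraded cues
than the sparse hippocampal one, the cortical recall curve has noisier
margins — its success rate is limited by attractor crosstalk, which is the
intended trade-off of a dense, generalizing store.

**Amygdala.** BA_N is sized to the sensory code (500 units, k = 50) and its
fixed SC projection is a seeded permutation, one cell per (feature, value)
bit: the overlap between two BA_N engrams equals the context feature overlap
*exactly*. This linearity is what makes the generalisation thresholds
interpretable (below). BA_N recurrent and HIP→BA_N plasticity open only when
|δ| > 0.05 (δ = US − CeA).

Valence cells: 100 P and 100 I binary threshold units. Learning is
`ΔW = η · |δ| · ℛ` on afferents from active BA_N cells (η = 0.35), capped
per synapse. The two caps are asymmetric by design:

- P: `w_max = 2.0`, threshold `θ_P = 50` — a fully recruited P-cell carries
  twice the drive it needs, because plasticity continues as long as a
  positive error persists. It therefore reactivates from ~50% context
  overlap.
- I: `w_max = 1.41`, threshold `θ_I = 60` — a fully recruited I-cell sits
  ~18% above threshold. Extinction stops as soon as fear is quenched (the
  error vanishes), so I-cells never accumulate a large excess and reactivate
  only above ~85% overlap. The cap window (θ_I/50 < w_max < K) also
  guarantees that consolidated extinction survives sleep homeostasis.

This threshold/cap asymmetry is the entire source of the
generalisation asymmetry (fear generalizes broadly, extinction narrowly)
and, through it, of renewal.

CeA is a memoryless sigmoid readout of the active-cell counts,
`σ(0.3 · (n_P − n_I − 10))`, clipped to 0 when no P-cell is active. The gain
was set so that fear saturates only near n_P ≈ 20, keeping the readout
sensitive in the range where partial engram reactivation moves a few cells
across threshold — a flat (saturated) readout would erase the graded
renewal ordering.

**Recruitability.** Each valence cell follows a square-wave eligibility
profile: high windows of 200 steps at a per-window amplitude drawn from
U(0.1, 1), separated by low phases (period jittered in 1200–1600 steps,
floor 0.03), with staggered phases so the population sum stays roughly
constant and only a minority of cells is highly recruitable at any moment.
Sparse single-step noise spikes (p = 0.003/cell/step) produce the weak,
incidental synapses that homeostasis is there to prune. The process is
phenomenological; only its statistics (window length, sparsity, stable sum)
are meaningful. The amplitude heterogeneity matters beyond realism: it
spreads afferent sums of recruited P-cells across the threshold–cap range,
which is what makes fear output *graded* in context overlap.

## Modes and update order

One Perception step: SC → (HIP, CTX, BA_N activation) → P/I activation →
CeA → prediction error → error-gated plasticity (BA_N recurrent, HIP→BA_N,
valence) → always-on plasticity (HIP recurrent, HIP→EC, HIP→CTX) →
recruitability and stress clocks. Recall probes run the same activation
cascade without any plasticity; fear is evaluated on the stimulus- plus
route-driven amygdala state, while memory retrieval is scored on the
recurrently converged state.

One Sleep step: HIP attractor update (recurrent − adaptation + Gaussian
drive jitter, σ = 2) → adaptation strengthening on the active set
(η = 0.12, decay 0.999/step, reset each night) → CTX reactivation slaved to
the replayed HIP drive (floor 13) → BA_N reactivation slaved to HIP→BA_N
drive (floor 10) → Hebbian consolidation of CTX recurrent and CTX→BA_N for
co-active cells. Two choices here are load-bearing:

- *Slaved reactivation.* CTX and BA_N follow the current hippocampal
  pattern feed-forward. Letting their own recurrent/learned afferents
  contribute during Sleep creates runaway incumbent assemblies that shadow
  later replay (observed, not hypothetical).
- *Coherence floors.* The reactivation floors are set above the drive a
  noisy mixture state can deliver, so only clean replay consolidates.
  Without them, late-night wandering (after adaptation has suppressed every
  attractor) smears cortical weights with mixture patterns and destroys
  remote recall.

A single 165-step night typically replays each stored engram one or more
times but can occasionally miss one memory; the replay-selectivity analyses
classify a Sleep step as a replay event when the active set is within 0.35
(1 − Jaccard) of a stored engram — far below the ≈ 0.95 distance between
distinct engrams.

After the replay loop, homeostasis integrates every nonzero valence weight
under the cubic rule and per-day decay is applied to all plastic
projections. Decay and the day counter advance even when sleep is skipped:
forgetting tracks time, not sleep.

## Sleep homeostasis

The rule `dx/dt = r·x·(1 − x/K)(x/A − 1)` with r = 1.4, A = 0.9, K = 1.7 has
stable fixed points at 0 and K and an unstable one at A. Integration is
explicit Euler at dt = 0.01 with total time 3.0 for a full night, scaled
linearly with sleep duration; a Runge–Kutta reference integrator
(`scipy.solve_ivp`) serves as the oracle in the test suite (agreement to
2·10⁻³ away from the unstable point). Weights below 10⁻³ after integration
are zeroed; after integration, weights are clipped to the projection cap
(relevant for I-synapses, whose cap lies below K). Only BA_N→P and BA_N→I
synapses are subject to homeostasis.

Stress: a US ≥ 1.0 sustained for ≥ 10 consecutive steps activates the
stress state, which multiplies P-cell recruitability by 3 and lowers the
extinction threshold on BA_N→P synapses to 0.45, both relaxing linearly to
baseline over 5 simulated days. Re-exposure refreshes the onset.

## Calibration and protocol scales

Free parameters without printed values were calibrated once, against the
qualitative targets they control, and are all config-exposed:

- `hip_day_decay = 0.945` — chosen with `scripts/calibrate_hip_decay.py` so
  that blurred-cue hippocampal recall fails completely at ~10 days of age
  (the 50% crossing lands near day 6; the failure age, not the crossing,
  is the anchored quantity).
- `eta_ctx_sleep = 0.12` and the coherence floor 13 — so the cortical
  recall curve rises over the first nights, peaks at 3–5 days and then
  declines slowly ("lower peak, flatter drop-off" than HIP).
- `η_valence = 0.35` — fast enough that a 3-step moderate US can recruit
  cells whose afferents carry residual subthreshold strength (the
  sensitization tests), slow enough that the error collapse during
  acquisition leaves a graded distribution of afferent sums (the renewal
  ordering).
- Phase durations of the protocols (e.g. 30-step acquisitions in the
  renewal family, 150 + 400 steps in the gradient protocol, 15 days ×
  2 contexts in the recall curve, 7 days × 3 contexts in the deprivation
  sweep) are this package's reconstruction of the experimental schedules,
  sized so that full Monte-Carlo repetitions stay inexpensive; every
  duration is a keyword argument.

Monte-Carlo repetition counts in the shipped analyses (10–30 seeds
depending on the effect size) were likewise chosen as the smallest samples
at which the reported orderings are stable.

## Known limitations

- No oscillatory microstructure of sleep (sharp-wave ripples, REM/SWS
  stages), no replay prioritization by valence, no cued (tone) conditioning
  pathway, no cortical-independent replay, and no CTX→HIP or BA→HIP
  feedback (hence no reconsolidation).
- The fear readout quantizes: with 100 binary P/I cells, CeA moves in
  steps of the sigmoid evaluated at integer counts. Orderings between
  conditions that differ by only one or two recruited cells are therefore
  Monte-Carlo statements over seeds, not per-run guarantees.
- The cortical route retrieves the conditioned amygdala engram essentially
  all-or-none once consolidation is complete, so remote generalized fear
  rises more steeply with consolidation than a graded readout would show.
- Sleep-deprivation sensitization of *acquisition speed* appears only after
  drastic sleep loss (the synaptic mass grows smoothly with deprivation,
  but the fear readout moves only once accumulated drive crosses
  threshold); analyses of the deprivation sweep should therefore lean on
  the synaptic-mass trend, which is the mechanistic quantity.
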