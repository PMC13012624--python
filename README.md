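# fearcons

A neural network simulator of **contextual fear conditioning with sleep**:
engram formation in hippocampus, neocortex and amygdala, replay-driven
systems consolidation, and synaptic homeostasis on the amygdala's
valence-coding synapses. It is aimed at computational neuroscientists who
want a compact, fully seeded model in which to study how context–fear
associations form during wakefulness, migrate from hippocampal–amygdalar to
cortico-amygdalar circuits across nights of sleep, generalize to similar
environments, and become pathologically sensitized when sleep or stress
disrupt overnight synaptic pruning.

## The model in brief

An environment (*context*) is a vector of F = 50 categorical features with
10 values each, represented one-hot in a sensory cortex layer (SC, 500
binary units). Three engram regions receive fixed projections from SC:

- **HIP** — sparse code (4% of 500 units, k-winner-take-all), fast bounded
  Hebbian recurrent plasticity, fast per-day forgetting. During *Sleep*,
  attractor dynamics plus a fast inhibitory "adaptation projection" make HIP
  cycle spontaneously through its stored engrams (replay).
- **CTX** — dense code (12%), negligible awake plasticity; its engrams are
  consolidated when hippocampal replay reactivates them overnight, and decay
  with a ~50-day half-life.
- **BA_N** — valence-neutral amygdala engram cells. Plasticity here (and on
  HIP→BA_N afferents) opens only when a *prediction error*
  `δ = US − CeA` is present.

Fear itself is carried by separate fear-promoting (P) and fear-inhibiting
(I) threshold cells: positive errors strengthen BA_N→P synapses, negative
errors BA_N→I, each scaled by the postsynaptic cell's slowly oscillating
*recruitability* ℛ. Active P/I cells excite/inhibit a single sigmoid fear
output (CeA). During *Recall*, an entorhinal match gate (F1 between input
and retrieved pattern) decides whether the hippocampal or the cortical route
drives the amygdala.

During *Sleep*, every BA_N→P/I synapse additionally evolves under a cubic
growth homeostasis rule

    dx/dt = r · x · (1 − x/K) · (x/A − 1),    r = 1.4, A = 0.9, K = 1.7

which is bistable: weights below the extinction threshold A are pruned to
0, weights above it are normalized toward the recruitment strength K.
Curtailed sleep performs only a partial renormalization; acute stress
transiently lowers A and boosts P-cell recruitability — the substrate of
sleep-deprivation sensitization and stress-enhanced fear learning (SEFL).

## Worked example

Fear acquisition and extinction in a single context (US on the first 20 of
70 steps):

```bash
$ fearcons run acq_ext --seed 1
 seed  peak_cea  final_cea  first_p_step  first_i_step
    1  0.645656   0.047426             5            26
```

The model acquires fear within a few steps of the first US (the first
fear-promoting cell activates at step 5, fear output peaking at 0.65 on a
0–1 scale). After the US is removed, fear-inhibiting cells need to
accumulate synaptic drive before they can fire, so extinction starts only
after a delay (first I-cell at step 26) and returns fear close to baseline
(0.047) by the end of the episode.

Renewal of extinguished fear in a fresh 80%-similar context:

```bash
fearcons run renewal -p paradigm=ABC --seed 0 --seed 1 --out runs/abc
fearcons report runs/abc
```

All eleven protocols (`fearcons list`) accept protocol parameters via
`-p key=value`, model parameters via `-m dotted.key=value`, and parameter
grids via `fearcons sweep … -g key=v1,v2,…`. The same registry is available
in Python:

```python
from fearcons import ProtocolConfig, run_protocol
res = run_protocol(ProtocolConfig("gradient", seeds=range(10)))
print(res.summaries.first_p_level.mean())   # ~0.5: P-cells generalize broadly
print(res.summaries.first_i_level.mean())   # ~0.9: extinction stays specific
```

Results are reproducible bit-exactly from (config, seed).

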