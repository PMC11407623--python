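# infodyn — information storage and transfer in microbial abundance time series

`infodyn` analyses longitudinal species-abundance data from microbial
communities as an information-processing system.  Each species is treated
as an agent whose "state" is its abundance; the package estimates, per
time step and in nats, how much of a species' next abundance value is

* stored in its own past — **local active information storage (AIS)**,
* transferred from the other species' pasts — **local apparent (TE) and
  collective (CTE) transfer entropy**, and
* irreducibly uncertain — **local intrinsic uncertainty (U)**,

so that the local entropy decomposes as `h = a + t + u`.  For a
destination X with history length k, source histories of length
l = k − 1 and a source–destination delay d,

```
a_X(x_{n+1}, x_n^(k))          = log p(x_{n+1} | x_n^(k)) / p(x_{n+1})
t_X(x_{n+1}, x_n^(k), v_{n+1-d}^(l)) = log p(x_{n+1} | x_n^(k), v_{n+1-d}^(l)) / p(x_{n+1} | x_n^(k))
u_X(x_{n+1}, x_n^(k), v_{n+1-d}^(l)) = -log p(x_{n+1} | x_n^(k), v_{n+1-d}^(l))
```

where `v` concatenates the delayed histories of all other species.  The
densities are estimated with the Kraskov–Stögbauer–Grassberger (KSG)
k-nearest-neighbour construction (max-norm, digamma corrections, tiny
tie-breaking noise), averaged over several noise realisations, with a
surrogate permutation test for significance.

The package ships a synthetic seven-species gut-community simulator
(Anaerostipes, Bacteroides, Bifidobacterium, Blautia, Clostridium,
Escherichia, Lactobacillus) — a discrete-time resource–consumer model
producing the characteristic phases of such data: growth after feeding
events, plateaus of constant abundance, starvation collapses with
absorbing extinctions, and a lone generalist survivor.  Two interventions
probe what transfer entropy detects: jittering a window of coherent
abundances (CTE drops) and injecting a metabolite hyper-producing strain
that boosts a target species two steps later (a producer→target TE peak
appears).

A practical pitfall the package automates away: any history-based local
measure produces *delayed effects* — echoes of a past event that surface
when the event leaves the conditioned k-step window, and therefore move
by exactly Δk when k grows by Δk.  `infodyn.effects` computes a signal at
three equally spaced history lengths, matches features across them and
labels each one `immediate` (stable at t, interpretable) or `delayed`
(shifting with k, an artefact).

## Worked example

```python
import numpy as np
from infodyn.community import single_plateau_series
from infodyn.measures import local_ais
from infodyn.effects import KVariantSet, classify_effects
from infodyn.tables import AnalysisConfig

x = single_plateau_series(length=150, change_step=101)   # one jump, then constant
cfg = AnalysisConfig(n_estimation_runs=25, rng_seed=0)
sigs = [local_ais(x, k, cfg, species="demo", seed=k) for k in (10, 15, 20)]
ann = classify_effects(KVariantSet("AIS", "demo", sigs), threshold=0.5)
print([f.step for f in ann.features["immediate"]],
      [f.step for f in ann.features["delayed"]], ann.shift)
```

prints

```
[101, 102] [111] 5
```

the AIS outlier at the abrupt change (step 101, with its rebound at 102)
is an immediate effect, stable across k, while the plateau-entry feature
appears at step 111 for k = 10 and recurs at 116 (k = 15) and 121
(k = 20): a delayed effect with shift 5.  The crossfeeding experiment
(`analysis/04_crossfeeding.py`) similarly prints, for k = 10, a
Clostridium→Bacteroides TE peak of 1.41 nats at step 32 in the
manipulated run (surrogate p ≈ 0.01) against 0.04 nats (p ≈ 0.49) in the
plain run.

## Repository layout

* `src/infodyn/` — the library: `community` (simulator + interventions),
  `tables` (CSV/YAML IO), `embedding`, `knn` (KSG engine), `measures`,
  `effects` (delayed/immediate classification), `pipeline` (scenario
  orchestration), `oracles` (test-only plug-in and closed-form
  references), `cli` (the `infodyn` command).
* `analysis/` — numbered drivers reproducing the study narrative:
  simulate, decompose, disturb coherence, enforce crossfeeding, classify
  effects.  Each writes tables/plots under `results/`.
* `docs/methods.md` — model, estimator and design notes.

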