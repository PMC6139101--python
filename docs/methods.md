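# Methods

## Model summary

The simulator iterates a five-dimensional map of psychological states —
emotions `E`, problem intensity `P`, motivation to change `M`, insight
`I`, therapeutic success `S` — under four trait parameters `a, c, r, m`
in [0, 1].  One iteration is one day.  All sixteen interaction functions
are built from the logistic primitive `sig(u) = 1/(1+e^u)`; their
literal gains, offsets and scales (including the 1.261 factor in the M
equation, kept verbatim) live in a single immutable constants table
(`EquationConstants`), dumpable as a flat key→value map for audit.

Assumptions baked into the state layer:

* **Synchronous update.**  Every equation reads only the t−1 state.  The
  published composite equations omit time indices; the one indexed
  example couples `E_t` to `S_{t-1}`, and we generalize that lag to all
  couplings.  Synchronicity makes the step order-independent and is
  asserted by test.
* **Internal ranges.**  Bipolar `E, S` live in [−1, 1], unipolar
  `P, M, I` in [0, 1] (configurable per scenario).  The admissible
  ranges are never stated; these are inferred from the sigmoid geometry
  (`e^{-10E}`, `e^{-20M+5}`, `P − 0.2 − 0.75(…)` only respond
  non-degenerately on spans of order one) and from the empirical ±100
  scale mapping (division by 100).  The pure map is *not* clamped —
  range enforcement happens in the engine after interventions and noise
  — so the map stays directly comparable to an independent
  transcription oracle.

## Trait dynamics

Each trait X is updated once per iteration (after the state step) as

```
p_t = p_{t-1} + s(Δ),   Δ = w_X · base · driver,
```

where `driver` is the trait-specific normalized combiner of the five
filter values `f_{E..S}` (and the cross-terms `r_{t-1}`, `c_{t-1}`),
`w_X = 0.004167` damps state-to-trait sensitivity, and `s(·)` is the
saturation/gating stage.  Numerical and interpretive choices:

* **Decay indexing.**  The printed filter exponent `e^{-λ(t-n+i)}`
  decays with *absolute* time, which would shrink all filter weights to
  zero as a run proceeds and contradicts the stated intent of weighting
  recent samples more than old ones.  We implement decay in sample
  *age*: weight `e^{-λ(n-i)}`, newest sample weight exactly 1.  This
  preserves the memory-effect semantics and makes the filter
  time-translation invariant.
* **The Δ in the saturation stage.**  The published text defines Δc as
  the difference between c_{t-1} and c_t, which is circular (c_t needs
  the saturated step).  We resolve Δ as the pre-saturation raw increment
  `w · p_{t-1} · driver` and apply the sign-gated saturation
  `s* = k·Δ·(p_max − p)` (growth) / `k·Δ·(p − p_min)` (decline) to it.
  The alternative literal reading (saturation as an extra multiplicative
  factor on the full equation) would square Δ and destroy the sign of
  decreases.
* **Threshold gating.**  Above `gate_high = 0.8` (growth) the step is
  additionally scaled by `(1 − p)`; below `gate_low = 0.2` (decline) by
  `(p − 1)` — as published.  The low-branch factor is negative, so near
  the floor a decline is turned into a small restoring push.  We keep
  this behavior by default (`literal_low_gate=True`) and expose
  `|p − 1|` as a configuration switch for sensitivity analysis.
* **Trait bounds.**  Only the interval for `c` (0.1 ≤ c ≤ 0.8, hence
  gain k = 0.7) is printed; the bounds of the other traits were chosen
  by bifurcation inspection that is out of scope here.  We default all
  four to (0.1, 0.8), overridable per trait.
* **Warm-up.**  The deviation filters need a full n = 14-day window.
  Traits are frozen for the first n iterations rather than computed from
  partial windows, so no starting instant is privileged.
* **Alliance mixing.**  `a' = ½(a_{t-1} + b_t)` replaces the
  multiplicative base of the a-update on every trait-update iteration
  when a b_t series is supplied; without data, `b_t := a_{t-1}` and the
  mix is the identity.  The mean-shift correction d = 0.535 is treated
  as a given constant; its derivation is not stated and is not
  re-derived here.
* **Exact filter null.**  Deviations are computed relative to the first
  window element before centering, so a constant window filters to
  exactly 0.0 in floating point (not merely to rounding error).

## Engine conventions

* Update order per iteration: state step → interventions → noise →
  clamp → trait update.  Interventions and noise act *on* the states,
  and the traits must see the realized (experienced) states.
* Interventions are additive shifts of magnitude/100 internal units
  ("+38 % on S" = 38 points on the 100-point empirical scale);
  overlapping events add.
* Dynamic noise is additive uniform on ±(level/100 · half range width)
  per variable (Gaussian optional); whether the published noise was
  additive or multiplicative, uniform or Gaussian, is unstated, so the
  convention is declared, configurable and recorded in every run
  manifest.  One master seed spawns independent per-variable substreams;
  silencing or adding one variable's perturbations never shifts
  another's sequence.
* Iterations are indexed from 0 (initial condition); interventions and
  noise first apply at t = 1, so caption t-values map directly.

## Reporting transforms

z-scores use the whole run and the sample (n−1) SD; a constant series
maps to zeros with a logged warning.  The gliding-window smoother is the
centered arithmetic mean (default width 3) with truncated windows at the
edges.  Transition summaries report per-variable pre/post means, SDs and
differences over two disjoint inclusive iteration intervals, on z or raw
views.

## Preset scenarios

The presets encode the published simulation experiments field by field
(initial values, trait values, noise levels, intervention windows).
Where a caption is internally inconsistent or silent the choice is
recorded here:

* `fig6b`: the continuous intervention window runs t = 17..25 (the body
  text); the caption's "from t = 27 to 25" contradicts itself.
* Run lengths are not printed; we use T = 200 (fig5), 100 (fig6a/b),
  150 (fig7), 300 (fig8, to cover the post-withdrawal recovery), 108
  (fig9, the length of the empirical episode), 400 (fig3, covering the
  comparison windows 0–100 and 250–400).
* `fig3` (competence ramp): the caption specifies only the c schedule
  (0.60, ramped linearly to 1.00 over iterations 100–200) with the
  endogenous trait dynamics disabled.  The initial states are the
  recurring baseline start (E 97.6, P 61.5, M 7.5, I 100, S −40.7), the
  other traits are pinned at the mid-range value 0.5, and dynamic noise
  is 10 % — a level used by the neighbouring experiments.  These values
  were fixed during design exploration so that the preset exhibits the
  documented phenomenon, a post-ramp drop of the mean level of E; with
  them the drop appears in every tested seed.

## What the map actually does

A systematic exploration of the printed equations (synchronous updates,
with or without clamping) shows that the deterministic map converges to
a fixed point for the overwhelming majority of trait combinations;
sustained oscillatory attractors exist only in small pockets of
(a, c, r, m) space and partly at state values outside the default clamp
ranges.  Chaotic oscillation at both ends of the c-ramp, as displayed in
the published figure, is not reachable with a single pinned (a, r, m)
under these conventions; the checkable content of that experiment — the
drop in the mean level of E — is what the preset and the acceptance
suite verify.  Within the clamped default ranges, several presets spend
long stretches at range boundaries (e.g. I at its ceiling), which the
z-transform reports as constant series.

## Synthetic data

`synth_alliance` generates daily alliance series (constant, linear, or
logistic growth from 0.3 to 0.8 with midpoint at T/2 — the typical
build-up of a working alliance over an episode), Gaussian-perturbed and
clipped to [0, 1].  `random_scenario` draws valid scenarios across the
full empirical ranges (traits in [0.05, 0.95], noise up to 30 %, up to
three random intervention events) for property testing.  These fixtures
emulate the *format* and coarse shape of real monitoring data, not its
autocorrelation or individual variability, so passing tests demonstrate
correctness of the machinery, determinism and boundedness — not
empirical adequacy for any client population.

## Problem sizes

The test and acceptance runs use 100 random inputs per oracle
comparison, 1000 random windows for the filter symmetries, 20 seeds for
the ramp experiment, and 200 random 1000-iteration scenarios for
boundedness/determinism; a 1000-iteration run takes on the order of
0.1 s on one CPU.
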