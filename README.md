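# crosskymo

Quantitative analysis of in vitro TIRF reconstitution experiments on
crosslinker-mediated actin–microtubule interactions: kymograph construction,
microtubule dynamic-instability statistics, FRAP off-rate estimation,
single-particle residence times, and rule-based classification of
actin-recruitment events — together with a synthetic-data generator
(dynamic-instability and binding-kinetics simulator plus TIRF-style
renderer) so every stage is testable end-to-end without raw imaging data.

It is aimed at experimentalists quantifying single-filament TIRF assays
(dynamic microtubules grown from stable GMPCPP seeds, diffusive
microtubule-associated binders such as anillin, actin co-recruitment) and at
anyone who needs a reference implementation of the standard kymograph-based
estimators.

## What it computes

**Dynamic instability.** From tip trajectories (manual anchor points or
automatic changepoint segmentation), growth/shrink speeds are aggregated
duration-weighted, wᵢ = dᵢ/Σd, v̄ = Σwᵢvᵢ, with standard error

    SE = sqrt( Σ w (Δx)² / ( ((N−1)/N) Σ w ) ),

Δxᵢ the deviation of each speed from v̄ and N the number of events.
Catastrophe and rescue frequencies are pooled — total transitions over total
time in the originating phase — with error = frequency/√n. Conditions are
compared with Welch's t test.

**FRAP.** Recovery traces are normalized as (I − min_post)/mean_pre and fit
to the reaction-limited model y = A(1 − e^(−k_off·t)) from the bleach point;
off-rate distributions are summarized by medians and compared with
Mann–Whitney U (exact small-sample p by full enumeration).

**Events.** Residence times (unbinding − landing, with censoring at movie
boundaries), a diffusion filter for static spots, and a four-way event
taxonomy — bind/unbind, lattice sliding, tip tracking, bundling — applied
with explicit kinematic rules (minimum presence 4 frames / 8 s,
crosslinker co-movement, precedence tip_tracking > bundling > sliding >
bind_unbind).

**Simulation.** Event-driven two-state microtubule dynamics (exponential
catastrophe/rescue waiting times, stable seed boundary), diffusive binders
with lattice-dependent off-rates (seed vs GDP lattice), FRAP forward model,
constructed crosslink events with ground-truth labels, and a renderer
(Gaussian PSF, Poisson + Gaussian noise) producing calibrated kymographs.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Run the shipped demo (simulates 50 microtubules, 120 FRAP traces in two
lattice conditions, and 40 labelled crosslink events, then analyses them):

```sh
crosskymo run --config configs/demo.toml --seed 1 --out demo_out
```

Abridged `summary.json` from that exact command:

```json
{
  "dynamics": {
    "growth_speed_um_min": 2.0,
    "catastrophe_frequency_s": 0.00388,
    "catastrophe_error_s": 0.000365,
    "rescue_frequency_s": 0.0290,
    "rescue_error_s": 0.00569,
    "n_catastrophes": 113
  },
  "frap": {
    "conditions": {
      "gdp":    {"median_k_off_s": 1.068, "n_used": 60},
      "gmpcpp": {"median_k_off_s": 0.272, "n_used": 60}
    },
    "tests": [{"pair": ["gdp", "gmpcpp"], "p_two_sided": 3.56e-21}]
  },
  "events": {"n_events": 40, "n_correctly_classified": 40, "accuracy": 1.0}
}
```

Reading it: the simulated growth speed (2 µm/min) is recovered exactly from
the noiseless phase log; the pooled catastrophe frequency 0.00388 s⁻¹ sits
within its counting error of the simulator input 0.004 s⁻¹ (the rescue
estimate 0.029 s⁻¹ vs input 0.02 s⁻¹ is within 2× its error — only 26
rescues were observed, most shrinkage ends at the seed). The median fitted
off-rate is ~4× higher on the GDP lattice (1.07 s⁻¹ truth) than on the
GMPCPP-like seed (0.26 s⁻¹ truth), a difference the Mann–Whitney test calls
at p ≈ 4 × 10⁻²¹, and all 40 constructed crosslink events are classified
correctly. Rerunning with the same seed reproduces the CSVs byte for byte.

The per-stage commands `crosskymo dynamics`, `crosskymo frap` and
`crosskymo events` run the same estimators on user-supplied CSV inputs; the
library functions in `crosskymo.dynamics`, `crosskymo.frapkit`,
`crosskymo.events`, `crosskymo.imagekit`, `crosskymo.simkit` and
`crosskymo.workbench` are the primary interface.

## Acceptance script

`scripts/acceptance.py` re-runs the full demo pipeline from scratch —
simulation, kymograph rendering, dynamics statistics, FRAP fitting and event
classification — under a caller-supplied seed and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The per-run tables and summary land in `results/demo_run/`.
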