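# Methods

`crosskymo` quantifies in vitro TIRF reconstitution experiments in which a
crosslinking protein (the motivating case is anillin) binds dynamic
microtubules and recruits actin filaments. Because raw imaging data for such
experiments are rarely deposited, the package pairs every analysis stage with
a simulator that generates ground-truth data with the statistical structure
the analysis assumes; all quantitative claims in the test suite are made
against that stated world.

## Microtubule dynamic instability

The simulator (`simkit.simulate_dynamic_instability`) is a two-state,
event-driven (Gillespie-type) model. A microtubule grows from a stabilized
seed at `v_growth` (µm/min) and switches to shrinkage at `v_shrink` with
exponential waiting times: catastrophe at rate `f_cat` (s⁻¹) while growing,
rescue at rate `f_res` while shrinking. Event-driven sampling keeps the
waiting-time distributions exact at any frame interval — a fixed-step Euler
scheme would bias short phases. There is no pause state in the simulator;
the analysis distinguishes only growth and shrinkage.

Seed boundary: shrinkage that reaches the seed stops there and regrowth is
forced. These restarts are logged as `seed_regrowth`, not rescue, because
seeds are stabilized lattice and rescue statistics refer to the dynamic
lattice only. Consequently the estimated rescue frequency is a conditional
rate (rescues per time spent shrinking *above* the seed), and matches the
input `f_res` only to the extent that shrink phases are not truncated by the
seed; the recovery tests use parameter regimes where truncation is mild and
compare within 3× the counting error.

Continuous trajectories are sampled onto frames using the true state at the
frame midpoint (`sample_trajectory`), which makes discretized phase
durations unbiased.

Default kinetic values (2 µm/min growth, 30 µm/min shrinkage, 0.004 s⁻¹
catastrophe, 0.02 s⁻¹ rescue, 600 s movies, 2 s/frame) are plausible for
dynamic microtubules grown from GMPCPP seeds at moderate tubulin
concentration; they are simulator inputs, not measurements, and recovery
tests compare estimates against whatever values were fed in.

## Dynamics statistics

Phase segments come either from manually picked anchor points
(`slopes_from_anchors`; one segment per anchor pair, speed = slope) or from
automatic piecewise-linear changepoint segmentation (`segment_auto`).
Segments with |speed| < 0.1 µm/min are labeled pauses and excluded from both
speed statistics and frequency exposure times.

Speeds are aggregated duration-weighted: wᵢ = dᵢ/Σd, mean = Σwᵢvᵢ (equal to
total displacement over total time), and

    SE = sqrt( Σ w Δx² / ( ((N−1)/N) Σ w ) ),

where Δxᵢ is the deviation of speed i from the weighted mean and N the
number of events. For N = 1 the SE is undefined (reported NaN). Σw is 1 by
construction but the formula is evaluated literally so it stays valid for
unnormalized weights.

Catastrophe and rescue frequencies are pooled: total transitions divided by
total time in the originating phase, with error = frequency/√n (undefined at
n = 0). A growth→pause→shrink sequence counts as one catastrophe. Groups are
compared with Welch's t test (unequal variances, Welch–Satterthwaite df).

`segment_auto` minimizes within-segment linear-fit RSS plus a per-breakpoint
penalty by optimal-partitioning dynamic programming (minimum segment length
3 samples). The default penalty is 6·σ̂²·log n with σ̂ estimated robustly
from second differences (MAD/0.6745/√6). The factor 6 — rather than a
textbook BIC factor of 2–3 — was calibrated so that pure-noise traces
produce no spurious growth/shrink segments (0/60 in calibration runs) while
transitions bounding phases of ≥3 frames remain detected. Shrink excursions
shorter than about one frame are intrinsically unresolvable at the default
2 s frame interval; frequency-recovery tests therefore use the simulator's
exact phase log, which is also what an experimentalist's manual anchor
points approximate.

## Binder kinetics and FRAP

`simulate_binder_tracks` attaches particles at Poisson times with rate
k_on × lattice length, diffuses them in 1-D (step SD √(2D·dt)), and detaches
them with the off-rate of the occupied region — `k_off_seed` on the
stabilized seed, `k_off_gdp` on the dynamic lattice (defaults 0.26 and
1.07 s⁻¹, the off-rate contrast that produces seed enrichment). Detachment
integrates the position-dependent hazard and interpolates the crossing time
of a unit-exponential threshold inside the step, so dwells on a homogeneous
lattice are exactly exponential regardless of dt. Track endpoints carry the
exact landing/unbinding times; only interior samples are frame-aligned. On a
static lattice particles reflect at both ends; on a dynamic lattice the
moving tip clamps rather than reflects, and lattice depolymerizing past a
particle forces release. Oligomer multiplicity only scales fluorescence
intensity (weights default 70% monomer / 20% dimer / 10% tetramer), not
kinetics.

FRAP recovery of a reaction-limited binder follows y(t) = A(1 − e^(−k_off·t)).
Traces are normalized by subtracting the post-bleach minimum and dividing by
the pre-bleach mean; the post-bleach minimum maps exactly to 0 and the fit's
time origin is that frame, consistent with the model having no offset term.
A is free in (0, 2] (recovery is typically incomplete), k_off is bounded in
[1e−4, 1e2] s⁻¹; initial values are A₀ = mean of the last 10% of points and
k₀ = ln2 / time-to-half-A₀. Fits that fail, land on the k bounds, or have
negative R² are flagged and excluded from condition medians (and counted).
Conditions are summarized by median k_off (the distributions are skewed) and
compared with a Mann–Whitney U test.

A known, accepted bias: subtracting the *noisy* post-bleach minimum raises
the whole curve by roughly the noise extreme (~2.5σ over ~100 frames), which
biases slow off-rates high — about +5% at k_off = 0.26 s⁻¹ with 5% noise,
under +2% at ≥0.7 s⁻¹. This is a property of the normalization convention
itself, so it is documented rather than corrected; recovery tests bound the
median at 10%.

## Event taxonomy

Residence time is the interval between landing on and unbinding from a
filament. Tracks present at the movie start or end are censored: excluded
from dwell summaries and counted separately, which guarantees no reported
dwell exceeds the movie duration. Static tracks (positional SD below 0.5 px
by default) are discarded before dwell analysis since an immobile spot is
indistinguishable from background.

A candidate actin–microtubule event must persist ≥4 frames (8 s at
2 s/frame) and co-move with the crosslinker channel (displacement
correlation ≥0.5 over shared frames). Classification applies the first
matching rule in the precedence order tip_tracking > bundling > sliding >
bind_unbind:

* **tip_tracking** — within 2 px of the microtubule tip for ≥4 consecutive
  frames, with mean crosslinker intensity ≥1.5× baseline;
* **bundling** — actin intensity ≥1.8× its initial baseline sustained for
  ≥4 frames (a second filament joining);
* **sliding** — net start-position displacement >3 px with |Spearman ρ| of
  position vs time ≥0.8;
* **bind_unbind** — the remainder.

The precedence order resolves tracks meeting several criteria; it is a
package choice (the taxonomy itself does not define one). Event location
(seed / GDP lattice / plus tip) is assigned from the landing-frame position
against the seed extent and tip position.

The synthetic event generator constructs tracks that satisfy exactly one
rule: near-zero net drift for bind/unbind, constant-velocity start motion for
sliding, tip-locked positions with elevated crosslinker intensity for tip
tracking, a mid-track sustained intensity step for bundling, each with a
co-moving companion crosslinker track. A green classifier round trip
therefore establishes that the rules are implemented as stated — not that
they are optimal for noisy real kymographs, where tracks are hand-traced and
the borderline cases the generator avoids do occur.

Overlap quantification thresholds the actin channel at background mean + 3σ
(per frame, from a user-supplied background band) inside the microtubule
extent; overlap length is the above-threshold column count × pixel size.
Channel intensities are background-subtracted and divided by their own
maximum (each normalized channel peaks at exactly 1); crosslinker enrichment
on overlaps is expressed relative to the mean crosslinker signal on bare
microtubule, which is 1 by construction.

## Kymographs and rendering

Kymographs are built by sampling each frame along a polyline at unit spacing
(bilinear interpolation; column count = round(arc length) + 1) and averaging
across an odd perpendicular width, default 5 px, offsets −2..+2, mean
projection. Out-of-bounds offset samples are dropped from the mean rather
than zero-padded. Coordinates are 0-based with pixel centers at integers;
time runs down the rows.

The renderer places each emitter as a unit-spaced sampling of a normalized
Gaussian (total mass = photons per fluorophore × intensity multiple; for
σ ≥ ~0.8 px the discrete mass equals the integral to well under 1%), with
σ = 0 collapsing to the nearest pixel. Poisson and/or additive Gaussian
camera noise follow, drawn from a generator seeded per run: identical seeds
give bit-identical images.

## Statistics

Mann–Whitney U uses mid-ranks. The exact two-sided p (used for n1+n2 ≤ 16
without ties, or on request) doubles the lower tail of min(U₁, U₂) under the
exact null distribution, computed by the standard counting recurrence —
equivalent to enumerating all C(n1+n2, n1) labelings — and caps at 1. With
ties or larger samples, the normal approximation with tie-corrected variance
and continuity correction is used; the branch taken is recorded in the
result. Welch's t is evaluated from the defining formulas. Identical-sample
and zero-variance degenerate cases return p = 1 (or a flagged p = 0 for
unequal means with zero variance) rather than erroring.

## Determinism

Every stochastic operation draws from a `numpy.random.Generator` seeded from
its parameter object or an explicit seed; the pipeline derives per-stage
seeds from the run seed. Rerunning the shipped demo configuration with the
same seed reproduces byte-identical CSV outputs (timing is reported but not
persisted).

## Limitations

* The simulators are 1-D along the filament axis: no 2-D filament
  geometries, crossings, zippering/breaking mechanics, or phase-separation
  behavior.
* Rescue frequency is conditional on shrinkage above the seed; regimes with
  frequent seed truncation under-sample long shrink phases.
* Auto-segmentation cannot resolve phases shorter than ~1 frame; manual
  anchors take precedence when supplied.
* The FRAP model is reaction-limited single-exponential only; diffusion-
  coupled or multi-exponential recoveries are out of scope.
* Particle tracks are inputs (from the simulator or external trackers); the
  package does not link spots in raw 2-D movies.
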