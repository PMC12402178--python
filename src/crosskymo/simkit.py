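"""Synthetic ground truth for kymograph-based crosslinking analysis.

Simulates the processes the downstream analysis assumes and renders them as
TIRF-style kymographs:

* two-state microtubule dynamic instability (exponential catastrophe /
  rescue waiting times, event-driven);
* a diffusive binder with first-order detachment whose off-rate differs
  between the stable seed and the dynamic GDP lattice;
* FRAP bleach-and-recovery of a reaction-limited binder;
* actin-filament recruitment events (bind/unbind, lattice sliding, tip
  tracking, bundling) constructed to satisfy the classifier's criteria;
* a renderer that convolves point emitters with a Gaussian PSF and adds
  Poisson and/or Gaussian camera noise.

All stochastic operations draw from one ``numpy.random.Generator`` seeded
from the parameter objects, so identical parameters give bit-identical
output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import (
    EVENT_LABELS,
    EventRecord,
    FilamentTrajectory,
    FrapTrace,
    Kymograph,
    ParticleTrack,
    PhaseSegment,
)

__all__ = [
    "DynamicsParams",
    "BinderParams",
    "OpticsParams",
    "StaticLattice",
    "GroundTruth",
    "simulate_dynamic_instability",
    "sample_trajectory",
    "simulate_binder_tracks",
    "simulate_frap_trace",
    "simulate_crosslink_events",
    "render_kymograph",
]

# transition labels written to the phase/event log
CATASTROPHE = "catastrophe"
RESCUE = "rescue"
SEED_REGROWTH = "seed_regrowth"  # shrinkage hit the seed; regrowth forced, not a rescue


def _check_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return v


@dataclass
class DynamicsParams:
    """Two-state dynamic-instability parameters.

    Speeds are in µm/min as reported for microtubule dynamics; rates in s⁻¹.
    Defaults are plausible values for dynamic microtubules grown from GMPCPP
    seeds at ~15 µM tubulin, not measurements.
    """

    v_growth: float = 2.0       # µm/min, > 0
    v_shrink: float = 30.0      # µm/min, stored positive
    f_cat: float = 0.004        # s⁻¹ catastrophe rate while growing
    f_res: float = 0.02         # s⁻¹ rescue rate while shrinking
    seed_length: float = 2.0    # µm of stable seed
    duration: float = 600.0     # s observed
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("v_growth", "v_shrink", "f_cat", "f_res", "seed_length", "duration"):
            setattr(self, name, _check_finite(name, getattr(self, name)))
        if self.v_growth <= 0 or self.v_shrink <= 0:
            raise ValueError("v_growth and v_shrink must be positive")
        if self.f_cat < 0 or self.f_res < 0:
            raise ValueError("rates must be non-negative")
        if self.seed_length < 0:
            raise ValueError("seed_length must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class BinderParams:
    """Diffusive binder (anillin-like) kinetics.

    The off-rate is lattice dependent: slower on the stable GMPCPP seed than
    on the dynamic GDP lattice, reproducing seed enrichment. Oligomer
    multiplicities only scale fluorescence intensity, not kinetics.
    """

    k_on: float = 0.05            # attachments per µm of lattice per s
    k_off_gdp: float = 1.07       # s⁻¹ on the GDP lattice
    k_off_seed: float = 0.26      # s⁻¹ on the GMPCPP seed
    diffusion_coeff: float = 0.05  # µm²/s along the lattice
    oligomer_weights: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.2, 4: 0.1})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off_gdp", "k_off_seed", "diffusion_coeff"):
            v = _check_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, v)
        total = sum(self.oligomer_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("oligomer_weights probabilities must sum to 1")
        if any(p < 0 for p in self.oligomer_weights.values()):
            raise ValueError("oligomer_weights probabilities must be non-negative")


@dataclass
class OpticsParams:
    """TIRF-style acquisition and camera model for the renderer."""

    pixel_size: float = 0.16       # µm per pixel
    frame_interval: float = 2.0    # s per frame
    psf_sigma: float = 1.0         # px, Gaussian PSF width
    photons_per_fluor: float = 200.0
    background_level: float = 20.0
    noise_model: str = "poisson+gaussian"  # poisson | gaussian | poisson+gaussian | none
    gaussian_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")
        if self.noise_model not in ("poisson", "gaussian", "poisson+gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class StaticLattice:
    """A non-dynamic filament: seed on [0, seed_end], GDP lattice beyond."""

    length: float
    seed_end: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if not 0 <= self.seed_end <= self.length:
            raise ValueError("seed_end must lie within [0, length]")


@dataclass
class GroundTruth:
    """Everything the renderer needs plus the labels the classifier must recover."""

    trajectory: FilamentTrajectory | None = None
    phase_log: list[PhaseSegment] = field(default_factory=list)
    transitions: list[tuple[float, str]] = field(default_factory=list)
    tracks: list[ParticleTrack] = field(default_factory=list)
    event_labels: list[EventRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dynamic instability


def simulate_dynamic_instability(
    params: DynamicsParams,
    rng: np.random.Generator | None = None,
) -> tuple[FilamentTrajectory, list[PhaseSegment], list[tuple[float, str]]]:
    """Event-driven two-state growth/shrinkage simulation.

    In the growth state the waiting time to catastrophe is exponential with
    rate ``f_cat``; in the shrink state the waiting time to rescue is
    exponential with rate ``f_res``. Shrinkage that reaches the seed forces
    regrowth and is logged as ``seed_regrowth``, not as a rescue, because the
    seed is stabilized and such restarts are not rescues on the dynamic
    lattice.

    Returns the tip trajectory (vertices at phase boundaries; positions
    measured from the seed minus end), the phase log and the transition log
    ``[(time, kind), ...]`` with kind in {catastrophe, rescue, seed_regrowth}.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    vg = params.v_growth / 60.0   # µm/s
    vs = params.v_shrink / 60.0

    t = 0.0
    length = 0.0  # dynamic lattice length above the seed
    state = "growth"
    times = [0.0]
    positions = [params.seed_length]
    phases: list[PhaseSegment] = []
    transitions: list[tuple[float, str]] = []

    while t < params.duration:
        if state == "growth":
            tau = rng.exponential(1.0 / params.f_cat) if params.f_cat > 0 else math.inf
            t_end = min(t + tau, params.duration)
            if t_end > t:
                phases.append(PhaseSegment("growth", t, t_end, params.v_growth))
                length += vg * (t_end - t)
                times.append(t_end)
                positions.append(params.seed_length + length)
            if t_end >= params.duration:
                break
            transitions.append((t_end, CATASTROPHE))
            state = "shrink"
            t = t_end
        else:
            tau_res = rng.exponential(1.0 / params.f_res) if params.f_res > 0 else math.inf
            t_seed = length / vs
            tau = min(tau_res, t_seed)
            t_end = min(t + tau, params.duration)
            if t_end > t:
                phases.append(PhaseSegment("shrink", t, t_end, -params.v_shrink))
                length = max(0.0, length - vs * (t_end - t))
                times.append(t_end)
                positions.append(params.seed_length + length)
            if t_end >= params.duration:
                break
            transitions.append((t_end, RESCUE if tau_res < t_seed else SEED_REGROWTH))
            state = "growth"
            t = t_end

    traj = FilamentTrajectory(np.array(times), np.array(positions), seed_reference=params.seed_length)
    return traj, phases, transitions


def sample_trajectory(
    traj: FilamentTrajectory, frame_interval: float, duration: float | None = None
) -> FilamentTrajectory:
    """Sample a continuous trajectory onto a frame grid.

    The tip position recorded for frame k is the true position at the frame
    midpoint ``(k + 1/2) * frame_interval``, which keeps phase durations
    unbiased; the sample is timestamped at the frame time ``k*frame_interval``.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if duration is None:
        duration = traj.duration
    n = int(math.floor(duration / frame_interval))
    frame_times = np.arange(n) * frame_interval
    mid = frame_times + frame_interval / 2.0
    return FilamentTrajectory(frame_times, traj.tip_at(mid), seed_reference=traj.seed_reference)


# ---------------------------------------------------------------------------
# diffusive binder


def _reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Fold positions into [0, length] by specular reflection."""
    if length <= 0:
        return np.zeros_like(x)
    period = 2.0 * length
    y = np.mod(x, period)
    return np.where(y > length, period - y, y)


def simulate_binder_tracks(
    params: BinderParams,
    lattice: StaticLattice | FilamentTrajectory,
    duration: float,
    frame_interval: float = 0.5,
) -> list[ParticleTrack]:
    """Simulate diffusive binder particles with lattice-dependent off-rates.

    Particles land at Poisson times with total rate ``k_on × lattice length``,
    diffuse in 1-D with ``diffusion_coeff`` and detach with the off-rate of
    the region they currently occupy (seed versus GDP lattice). Detachment is
    generated by integrating the position-dependent hazard and interpolating
    the crossing time of a unit-exponential threshold within the step, so
    dwells on a homogeneous lattice are exactly exponential.

    Each returned track's first and last samples are the exact landing and
    unbinding times; intermediate samples fall on the frame grid. The track
    intensity is a constant multiple drawn from ``oligomer_weights``.
    """
    rng = np.random.default_rng(params.rng_seed)
    dynamic = isinstance(lattice, FilamentTrajectory)
    if dynamic:
        seed_end = lattice.seed_reference
        length_max = float(np.max(lattice.tip_positions))
        def tip_at(t: float) -> float:
            return float(lattice.tip_at(t))
    else:
        seed_end = lattice.seed_end
        length_max = lattice.length
        def tip_at(t: float) -> float:
            return length_max

    if length_max <= 0:
        import warnings

        warnings.warn("zero-length lattice: no binder tracks generated", stacklevel=2)
        return []

    # Poisson arrivals over [0, duration); thinned by current length for a
    # dynamic lattice so the landing flux follows the available lattice.
    rate_max = params.k_on * length_max
    n_arrivals = rng.poisson(rate_max * duration)
    arrival_times = np.sort(rng.uniform(0.0, duration, n_arrivals))
    mult_values = np.array(list(params.oligomer_weights.keys()), dtype=float)
    mult_probs = np.array(list(params.oligomer_weights.values()), dtype=float)

    dt = frame_interval
    sigma_step = math.sqrt(2.0 * params.diffusion_coeff * dt)
    tracks: list[ParticleTrack] = []

    for i, t0 in enumerate(arrival_times):
        tip0 = tip_at(t0)
        if dynamic and rng.uniform() > tip0 / length_max:
            continue  # thinning: lattice shorter than maximum at this instant
        x = rng.uniform(0.0, tip0)
        mult = float(rng.choice(mult_values, p=mult_probs))
        threshold = rng.exponential(1.0)

        ts = [t0]
        xs = [x]
        hazard = 0.0
        t = t0
        detached = False
        t_off = duration
        x_off = x
        while t < duration and not detached:
            step_dt = min(dt, duration - t)
            k_local = params.k_off_seed if x <= seed_end else params.k_off_gdp
            h_step = k_local * step_dt
            if hazard + h_step >= threshold and h_step > 0:
                frac = (threshold - hazard) / h_step
                t_off = t + frac * step_dt
                x_off = x  # position at detachment (before the diffusive step)
                detached = True
                break
            hazard += h_step
            x_new = x + (rng.normal(0.0, sigma_step) if sigma_step > 0 else 0.0)
            t = t + step_dt
            tip_now = tip_at(t)
            if dynamic:
                x_new = min(max(x_new, 0.0), length_max)
                if x_new > tip_now:
                    # lattice depolymerized past the particle: forced release
                    t_off = t
                    x_off = x
                    detached = True
                    break
            else:
                x_new = float(_reflect(np.array([x_new]), length_max)[0])
            x = x_new
            if t < duration:
                ts.append(t)
                xs.append(x)
            else:
                t_off = duration
                x_off = x
        if not detached:
            t_off = duration
            x_off = x
        if t_off > ts[-1]:
            ts.append(t_off)
            xs.append(x_off)
        n = len(ts)
        tracks.append(
            ParticleTrack(
                track_id=f"binder_{i:05d}",
                times=np.array(ts),
                positions=np.array(xs),
                intensities=np.full(n, mult),
                channel="binder",
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# FRAP


def simulate_frap_trace(
    k_off: float,
    plateau: float = 0.8,
    n_prebleach: int = 55,
    frame_interval: float = 0.2,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    n_postbleach: int = 300,
    roi_id: str = "",
    condition: str = "",
) -> FrapTrace:
    """Forward model of a reaction-limited FRAP experiment.

    Pre-bleach frames sit at 1.0 (scaled units); the bleach frame drops to 0
    instantaneously and recovery follows ``plateau * (1 - exp(-k_off * t))``
    with additive Gaussian noise of standard deviation ``noise_sigma``.
    """
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    if not 0 < plateau <= 1:
        raise ValueError("plateau must be in (0, 1]")
    if n_prebleach < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    n = n_prebleach + n_postbleach
    times = np.arange(n) * frame_interval
    intensities = np.ones(n)
    t_post = times[n_prebleach:] - times[n_prebleach]
    intensities[n_prebleach:] = plateau * (1.0 - np.exp(-k_off * t_post))
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        intensities = intensities + rng.normal(0.0, noise_sigma, n)
    return FrapTrace(times, intensities, bleach_index=n_prebleach, roi_id=roi_id, condition=condition)


# ---------------------------------------------------------------------------
# crosslink event construction


def _grid(t_start: float, n_frames: int, frame_interval: float) -> np.ndarray:
    return t_start + np.arange(n_frames) * frame_interval


def simulate_crosslink_events(
    event_spec: Sequence[dict],
    mt: FilamentTrajectory,
    frame_interval: float = 2.0,
    rng_seed: int = 0,
    jitter_px: float = 0.2,
    pixel_size: float = 0.16,
) -> tuple[list[ParticleTrack], list[EventRecord]]:
    """Construct labelled actin-recruitment events on a microtubule.

    ``event_spec`` rows are dicts with at least ``label`` (one of
    bind_unbind / sliding / tip_tracking / bundling) and optionally
    ``t_start`` (s), ``n_frames``, ``slide_speed`` (µm/s), ``position`` (µm),
    ``step_factor``. Each constructed track satisfies its label's defining
    criterion by construction; a companion anillin track co-moving with the
    actin track is emitted for every event (ids ``<event>_actin`` and
    ``<event>_anillin``).
    """
    rng = np.random.default_rng(rng_seed)
    jitter = jitter_px * pixel_size
    tracks: list[ParticleTrack] = []
    records: list[EventRecord] = []
    mt_t0, mt_t1 = float(mt.times[0]), float(mt.times[-1])
    for idx, spec in enumerate(event_spec):
        label = spec.get("label")
        if label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {label!r}")
        n_frames = int(spec.get("n_frames", 10))
        t_start = float(spec.get("t_start", mt_t0 + rng.uniform(0.0, max(mt_t1 - mt_t0 - n_frames * frame_interval, 0.0))))
        times = _grid(t_start, n_frames, frame_interval)
        times = times[times <= mt_t1]
        n = times.size
        tip = mt.tip_at(times)
        base_pos = float(spec.get("position", max(mt.seed_reference, np.min(tip) * 0.5)))
        intens = np.ones(n)

        if label == "tip_tracking":
            pos = tip + rng.normal(0.0, jitter, n)
        elif label == "sliding":
            v = float(spec.get("slide_speed", 0.1))  # µm/s
            pos = base_pos + v * (times - times[0]) + rng.normal(0.0, jitter, n)
        elif label == "bundling":
            pos = base_pos + rng.normal(0.0, jitter, n)
            factor = float(spec.get("step_factor", 2.5))
            k = max(n // 2, 1)
            intens = np.ones(n)
            intens[k:] = factor  # second filament arrives: stable intensity step
        else:  # bind_unbind
            pos = base_pos + np.cumsum(rng.normal(0.0, jitter, n))
            pos = pos - (pos[-1] - pos[0]) * np.linspace(0.0, 1.0, n)  # zero net drift
        pos = np.clip(pos, 0.0, None)

        eid = f"ev{idx:03d}"
        actin = ParticleTrack(f"{eid}_actin", times, pos, intens, channel="actin")
        # companion crosslinker track: rides the actin filament almost exactly
        # so the co-movement criterion holds by construction
        anillin = ParticleTrack(
            f"{eid}_anillin",
            times,
            pos + rng.normal(0.0, jitter * 0.1, n),
            np.ones(n) * (2.0 if label == "tip_tracking" else 1.0),
            channel="anillin",
        )
        tracks.extend([actin, anillin])
        n_fil = 2 if label == "bundling" else 1
        if pos[0] <= mt.seed_reference:
            loc = "seed"
        elif abs(pos[0] - tip[0]) <= 2 * pixel_size:
            loc = "plus_tip"
        else:
            loc = "gdp_lattice"
        records.append(EventRecord(eid, label, float(times[0]), float(times[-1]), n_filaments=n_fil, location=loc))
    return tracks, records


# ---------------------------------------------------------------------------
# rendering


def render_kymograph(
    truth: GroundTruth,
    optics: OpticsParams,
    duration: float | None = None,
    n_positions: int | None = None,
    channel: str = "binder",
    rng_seed: int = 0,
) -> Kymograph:
    """Render one channel of the ground truth as a kymograph.

    Rows are frames, columns are positions along the filament axis. Each
    emitter present in a frame contributes a Gaussian of total mass
    ``photons_per_fluor × intensity multiple`` (unit-spaced samples of the
    normalized Gaussian); ``psf_sigma = 0`` puts all photons in the nearest
    pixel. The microtubule channel (``channel="microtubule"``) renders one
    emitter per pixel-sized site of the lattice, with doubled brightness on
    the seed.
    """
    tracks = [tr for tr in truth.tracks if tr.channel == channel]
    if duration is None:
        candidates = [tr.t_off for tr in tracks]
        if truth.trajectory is not None:
            candidates.append(float(truth.trajectory.times[-1]))
        duration = max(candidates) if candidates else 0.0
    n_frames = max(int(math.floor(duration / optics.frame_interval)) + 1, 1)
    if n_positions is None:
        extent = [np.max(tr.positions, initial=0.0) for tr in tracks]
        if truth.trajectory is not None:
            extent.append(float(np.max(truth.trajectory.tip_positions)))
        max_um = max(extent) if extent else 1.0
        n_positions = int(math.ceil(max_um / optics.pixel_size)) + 8

    frame_times = np.arange(n_frames) * optics.frame_interval
    img = np.full((n_frames, n_positions), float(optics.background_level))
    cols = np.arange(n_positions, dtype=float)

    def add_emitter(row: int, pos_px: float, photons: float) -> None:
        if optics.psf_sigma == 0:
            j = int(round(pos_px))
            if 0 <= j < n_positions:
                img[row, j] += photons
        else:
            s = optics.psf_sigma
            prof = np.exp(-0.5 * ((cols - pos_px) / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
            img[row] += photons * prof

    if channel == "microtubule" and truth.trajectory is not None:
        traj = truth.trajectory
        mid = frame_times + optics.frame_interval / 2.0
        tip_px = traj.tip_at(np.clip(mid, traj.times[0], traj.times[-1])) / optics.pixel_size
        seed_px = traj.seed_reference / optics.pixel_size
        for r in range(n_frames):
            lattice_cols = cols[cols <= tip_px[r]]
            for c in lattice_cols:
                add_emitter(r, c, optics.photons_per_fluor * (2.0 if c <= seed_px else 1.0))
    else:
        for tr in tracks:
            # emitter is present in frames whose midpoint falls inside the dwell
            mid = frame_times + optics.frame_interval / 2.0
            mask = (mid >= tr.t_on) & (mid <= tr.t_off)
            rows = np.nonzero(mask)[0]
            if rows.size == 0:
                continue
            pos_px = np.interp(mid[rows], tr.times, tr.positions) / optics.pixel_size
            inten = np.interp(mid[rows], tr.times, tr.intensities)
            for r, p, m in zip(rows, pos_px, inten):
                add_emitter(int(r), float(p), optics.photons_per_fluor * float(m))

    rng = np.random.default_rng(rng_seed)
    if optics.noise_model in ("poisson", "poisson+gaussian"):
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if optics.noise_model in ("gaussian", "poisson+gaussian") and optics.gaussian_sigma > 0:
        img = img + rng.normal(0.0, optics.gaussian_sigma, img.shape)
    return Kymograph(img, optics.pixel_size, optics.frame_interval, channel=channel)
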