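"""Dynamic-instability statistics from microtubule tip trajectories.

Growth and shrink speeds are duration-weighted: each phase's weight is its
duration divided by the total time in phases of that kind, the mean is the
weighted sum of speeds, and the standard error is

    SE = sqrt( Σ w·Δx² / ( ((N−1)/N) · Σ w ) )

with Δx the deviation of each speed from the weighted mean and N the number
of events. Catastrophe (growth→shrink) and rescue (shrink→growth)
frequencies are pooled — total transition count divided by total time spent
in the originating phase — with error = frequency / √n.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import GROWTH, PAUSE, SHRINK, FrequencyEstimate, FilamentTrajectory, PhaseSegment, SpeedStats
from .workbench import welch_t

__all__ = [
    "slopes_from_anchors",
    "segment_auto",
    "weighted_speed",
    "event_frequencies",
    "count_transitions",
    "compare_dynamics",
    "DEFAULT_PAUSE_BAND",
]

DEFAULT_PAUSE_BAND = 0.1  # µm/min; |speed| below this is a pause


def _kind_from_speed(speed_um_min: float, pause_band: float) -> str:
    if abs(speed_um_min) < pause_band:
        return PAUSE
    return GROWTH if speed_um_min > 0 else SHRINK


def slopes_from_anchors(
    anchors: Sequence[tuple[float, float]], pause_band: float = DEFAULT_PAUSE_BAND
) -> list[PhaseSegment]:
    """Phase segments from manually picked (position µm, time s) anchor points.

    One segment per consecutive anchor pair; the speed is the slope
    Δposition/Δtime converted to µm/min, and the phase kind follows the sign
    of the speed with a ±``pause_band`` µm/min dead band.
    """
    a = np.asarray(anchors, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise ValueError("need at least two (position, time) anchors")
    pos, t = a[:, 0], a[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("anchor times must be strictly increasing (duplicate times?)")
    speeds = np.diff(pos) / dt * 60.0
    return [
        PhaseSegment(_kind_from_speed(v, pause_band), float(t0), float(t1), float(v))
        for v, t0, t1 in zip(speeds, t[:-1], t[1:])
    ]


# ---------------------------------------------------------------------------
# automatic changepoint segmentation


def _segment_rss_factory(t: np.ndarray, x: np.ndarray):
    """O(1) residual sum of squares of a linear fit on any window [i, j)."""
    c1 = np.concatenate([[0.0], np.cumsum(np.ones_like(t))])
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cx = np.concatenate([[0.0], np.cumsum(x)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    ctx = np.concatenate([[0.0], np.cumsum(t * x)])

    def rss(i: np.ndarray, j: int) -> np.ndarray:
        n = c1[j] - c1[i]
        st = ct[j] - ct[i]
        sx = cx[j] - cx[i]
        stt = ctt[j] - ctt[i]
        sxx = cxx[j] - cxx[i]
        stx = ctx[j] - ctx[i]
        den = n * stt - st * st
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(den > 0, (n * stx - st * sx) / den, 0.0)
            intercept = (sx - slope * st) / n
        r = sxx - 2 * slope * stx - 2 * intercept * sx + slope**2 * stt + 2 * slope * intercept * st + n * intercept**2
        return np.maximum(r, 0.0)

    return rss


def _noise_variance(x: np.ndarray) -> float:
    """Robust noise variance from second differences (slope-insensitive)."""
    d2 = np.diff(x, 2)
    if d2.size == 0:
        return 0.0
    mad = np.median(np.abs(d2 - np.median(d2)))
    sigma = mad / 0.6745 / math.sqrt(6.0)
    return float(sigma**2)


def segment_auto(
    traj: FilamentTrajectory,
    penalty: float | None = None,
    pause_band: float = DEFAULT_PAUSE_BAND,
    min_size: int = 3,
) -> list[PhaseSegment]:
    """Piecewise-linear changepoint segmentation of a tip trajectory.

    Minimizes total within-segment linear-fit RSS plus ``penalty`` per
    breakpoint by dynamic programming (optimal partitioning). The default
    penalty is BIC-like, ``6 σ̂² log n`` with σ̂² estimated robustly from
    second differences; the factor 6 (rather than the textbook 2–3) accounts
    for the breakpoint location being optimized along with the two line
    parameters and holds the spurious-phase rate on pure noise near zero. Segments are labelled by fitted slope as in
    :func:`slopes_from_anchors`; adjacent segments of equal kind are merged.
    """
    t = np.asarray(traj.times, dtype=float)
    x = np.asarray(traj.tip_positions, dtype=float)
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 trajectory samples")
    if np.allclose(x, x[0]):
        return [PhaseSegment(PAUSE, float(t[0]), float(t[-1]), 0.0)]
    if penalty is None:
        penalty = 6.0 * _noise_variance(x) * math.log(n)
        if penalty == 0:
            penalty = 1e-12
    rss = _segment_rss_factory(t, x)

    # optimal partitioning: cost[j] = best cost of segmenting x[:j]
    cost = np.full(n + 1, np.inf)
    cost[0] = -penalty  # first segment pays no breakpoint penalty
    back = np.zeros(n + 1, dtype=int)
    for j in range(min_size, n + 1):
        i = np.arange(0, j - min_size + 1)
        c = cost[i] + penalty + rss(i, j)
        k = int(np.argmin(c))
        cost[j] = c[k]
        back[j] = i[k]

    # recover breakpoints
    bounds = [n]
    j = n
    while j > 0:
        j = back[j]
        bounds.append(j)
    bounds = bounds[::-1]

    segments: list[PhaseSegment] = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        tt, xx = t[i:j], x[i:j]
        slope = float(np.polyfit(tt, xx, 1)[0]) * 60.0  # µm/min
        t0 = float(t[i]) if i == 0 else float((t[i - 1] + t[i]) / 2.0)
        t1 = float(t[j - 1]) if j == n else float((t[j - 1] + t[j]) / 2.0)
        segments.append(PhaseSegment(_kind_from_speed(slope, pause_band), t0, t1, slope))

    # merge adjacent same-kind segments (duration-weighted speed)
    merged: list[PhaseSegment] = []
    for seg in segments:
        if merged and merged[-1].kind == seg.kind:
            prev = merged.pop()
            w1, w2 = prev.duration, seg.duration
            v = (prev.speed * w1 + seg.speed * w2) / (w1 + w2)
            merged.append(PhaseSegment(seg.kind, prev.t_start, seg.t_end, v))
        else:
            merged.append(seg)
    return merged


# ---------------------------------------------------------------------------
# aggregate statistics


def weighted_speed(segments: Iterable[PhaseSegment], kind: str = GROWTH) -> SpeedStats:
    """Duration-weighted mean speed and weighted SE for one phase kind.

    Weights are each event's duration divided by the total duration, so they
    sum to 1, but the SE formula is evaluated literally with Σw in the
    denominator and remains valid for unnormalized weights.
    """
    segs = [s for s in segments if s.kind == kind]
    if not segs:
        raise ValueError(f"no segments of kind {kind!r}")
    d = np.array([s.duration for s in segs])
    v = np.array([s.speed for s in segs])
    w = d / d.sum()
    mean = float(np.sum(w * v))
    dx = v - mean
    n = len(segs)
    if n == 1:
        se = float("nan")
    else:
        se = float(math.sqrt(np.sum(w * dx**2) / (((n - 1) / n) * np.sum(w))))
    return SpeedStats(mean, se, n, w, dx)


def count_transitions(segments: Sequence[PhaseSegment]) -> tuple[int, int]:
    """Catastrophes and rescues inferred from an ordered segment list.

    A growth→shrink transition between adjacent non-pause segments is a
    catastrophe and shrink→growth a rescue; a single intervening pause does
    not break the transition (growth→pause→shrink is one catastrophe).
    """
    kinds = [s.kind for s in segments]
    n_cat = n_res = 0
    prev = None
    for k in kinds:
        if k == PAUSE:
            continue
        if prev == GROWTH and k == SHRINK:
            n_cat += 1
        elif prev == SHRINK and k == GROWTH:
            n_res += 1
        prev = k
    return n_cat, n_res


def _frequency(n_events: int, exposure: float) -> FrequencyEstimate:
    if exposure <= 0:
        return FrequencyEstimate(float("nan"), float("nan"), n_events, exposure)
    f = n_events / exposure
    err = f / math.sqrt(n_events) if n_events >= 1 else float("nan")
    return FrequencyEstimate(f, err, n_events, exposure)


def event_frequencies(
    segments: Sequence[PhaseSegment] | Sequence[Sequence[PhaseSegment]],
    transitions: Sequence[tuple[float, str]] | None = None,
) -> tuple[FrequencyEstimate, FrequencyEstimate]:
    """Pooled catastrophe and rescue frequencies with errors.

    ``segments`` may be one microtubule's segment list or a list of lists
    (pooled: total events over total exposure). If explicit ``transitions``
    logs are supplied (e.g. from the simulator) they are counted instead of
    being inferred from segment order; seed-regrowth events are never counted
    as rescues. Pause time is excluded from exposure.
    """
    if segments and isinstance(segments[0], PhaseSegment):
        per_mt = [list(segments)]  # type: ignore[list-item]
        trans_per_mt = [transitions] if transitions is not None else None
    else:
        per_mt = [list(s) for s in segments]  # type: ignore[union-attr]
        trans_per_mt = transitions  # type: ignore[assignment]

    t_grow = sum(s.duration for mt in per_mt for s in mt if s.kind == GROWTH)
    t_shrink = sum(s.duration for mt in per_mt for s in mt if s.kind == SHRINK)
    n_cat = n_res = 0
    if trans_per_mt is not None:
        for log in trans_per_mt:
            for _, kind in log:
                if kind == "catastrophe":
                    n_cat += 1
                elif kind == "rescue":
                    n_res += 1
    else:
        for mt in per_mt:
            c, r = count_transitions(mt)
            n_cat += c
            n_res += r
    return _frequency(n_cat, t_grow), _frequency(n_res, t_shrink)


def compare_dynamics(groups: Mapping[str, Sequence[float]], metric: str = "speed") -> dict:
    """Welch t comparison of a dynamics metric between conditions.

    Returns a report dict with per-group mean/sd/n and the pairwise Welch
    two-sided p-values; groups with fewer than two values are flagged and
    excluded from testing.
    """
    report: dict = {"metric": metric, "groups": {}, "tests": []}
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        entry = {"n": int(arr.size), "mean": float(arr.mean()) if arr.size else float("nan")}
        if arr.size >= 2:
            entry["sd"] = float(arr.std(ddof=1))
            clean[name] = arr
        else:
            entry["flag"] = "insufficient n for Welch t"
        report["groups"][name] = entry
    names = list(clean)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = welch_t(clean[names[i]], clean[names[j]])
            report["tests"].append(
                {
                    "pair": [names[i], names[j]],
                    "t": res.statistic,
                    "p_two_sided": res.p_two_sided,
                    "method": res.method,
                }
            )
    return report
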