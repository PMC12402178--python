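"""Statistical tests and the pipeline/report glue.

Mann–Whitney U with an exact small-sample two-sided p (full enumeration of
the null rank-sum distribution) and Welch's unequal-variance t test, plus
the run_pipeline driver that ties simulation, kymograph construction,
dynamics, FRAP and event analysis into one reproducible run.
"""
from __future__ import annotations

import hashlib
import json
import math
import time
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import TestResult

__all__ = ["mann_whitney_u", "welch_t", "exact_u_distribution", "run_pipeline", "load_config"]

EXACT_LIMIT = 16  # use exact enumeration when n1 + n2 <= this and no ties


def exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the Mann–Whitney U statistic.

    ``out[u]`` is the number of the C(n1+n2, n1) equally likely rank
    assignments giving U = u. Computed by the standard partition recurrence,
    which enumerates the full null distribution exactly.
    """
    # N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1), by whether the largest
    # rank belongs to the first or second sample; base cases m=0 or n=0 put
    # all mass at U=0. Equivalent to enumerating all C(n1+n2, n1) labelings.
    max_u = n1 * n2
    prev = np.zeros((n1 + 1, max_u + 1))
    prev[:, 0] = 1.0  # n = 0
    for n in range(1, n2 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for m in range(1, n1 + 1):
            cur[m] = prev[m]
            cur[m, n:] = cur[m, n:] + cur[m - 1, : max_u + 1 - n]
        prev = cur
    return prev[n1]


def mann_whitney_u(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> TestResult:
    """Mann–Whitney U test with exact small-sample two-sided p.

    U is computed from mid-ranked rank sums. The exact two-sided p doubles
    the one-sided tail of min(U_x, U_y) under the enumerated null (capped at
    1) and is used when n1+n2 <= 16 with no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used. ``mode`` forces one branch ("exact" / "normal").
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    n1, n2 = xa.size, ya.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([xa, ya])
    if np.all(combined == combined[0]):
        return TestResult(n1 * n2 / 2.0, 1.0, "mann_whitney_exact", n1, n2,
                          note="all values identical; p=1 by convention")
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = np.unique(combined).size < combined.size

    use_exact = (mode == "exact") or (mode == "auto" and n1 + n2 <= EXACT_LIMIT and not has_ties)
    if use_exact and has_ties:
        use_exact = False  # exact enumeration assumes distinct values
    if use_exact:
        dist = exact_u_distribution(n1, n2)
        total = dist.sum()
        u_min = min(u1, u2)
        k = int(round(u_min))
        p_one = dist[: k + 1].sum() / total
        p = min(1.0, 2.0 * p_one)
        return TestResult(u1, float(p), "mann_whitney_exact", n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u1, 1.0, "mann_whitney_normal", n1, n2, note="zero variance")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)  # continuity corrected
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return TestResult(u1, float(min(p, 1.0)), "mann_whitney_normal", n1, n2)


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's two-sample t test (unequal variances), two-sided.

    t = (x̄ − ȳ) / sqrt(s1²/n1 + s2²/n2) with Welch–Satterthwaite degrees of
    freedom; the df is recorded in the result's note field.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    n1, n2 = xa.size, ya.size
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch t requires at least two values per sample")
    v1 = xa.var(ddof=1)
    v2 = ya.var(ddof=1)
    dm = xa.mean() - ya.mean()
    if v1 == 0 and v2 == 0:
        if dm == 0:
            return TestResult(0.0, 1.0, "welch_t", n1, n2, note="zero variance in both samples")
        return TestResult(math.copysign(math.inf, dm), 0.0, "welch_t", n1, n2,
                          note="degenerate: zero variance, unequal means")
    se2 = v1 / n1 + v2 / n2
    t = dm / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), "welch_t", n1, n2, note=f"df={df:.10g}")


# ---------------------------------------------------------------------------
# pipeline


def load_config(path) -> dict:
    """Read a TOML run configuration."""
    import tomllib

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config not found: {p}")
    with open(p, "rb") as fh:
        return tomllib.load(fh)


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run simulate → kymograph → dynamics / FRAP / events → statistics.

    Writes trajectories, phase logs, tracks, FRAP fits, classified events
    and a manifest (config, seed, checksums) under ``out_dir``; returns the
    summary dict. Re-running with the same config and seed reproduces
    byte-identical CSV outputs.
    """
    import pandas as pd
    import tifffile

    from . import dynamics as dyn
    from . import events as ev
    from . import frapkit, simkit

    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("run", {}).get("seed", 0))
    summary: dict = {"seed": seed}
    warnings_log: list[str] = []

    # --- stage 1: dynamic instability ensemble -----------------------------
    dcfg = dict(config.get("dynamics", {}))
    n_mt = int(dcfg.pop("n_microtubules", 50))
    frame_interval = float(config.get("optics", {}).get("frame_interval", 2.0))
    traj_rows, seg_rows = [], []
    all_segments, all_transitions = [], []
    first_traj = None
    for m in range(n_mt):
        params = simkit.DynamicsParams(**dcfg, rng_seed=seed * 100003 + m)
        traj, phases, transitions = simkit.simulate_dynamic_instability(params)
        if first_traj is None:
            first_traj = traj
        sampled = simkit.sample_trajectory(traj, frame_interval, params.duration)
        for t, x in zip(sampled.times, sampled.tip_positions):
            traj_rows.append({"trajectory_id": m, "t_s": t, "tip_position_um": x})
        for s in phases:
            seg_rows.append(
                {"trajectory_id": m, "kind": s.kind, "t_start_s": s.t_start,
                 "t_end_s": s.t_end, "speed_um_min": s.speed}
            )
        all_segments.append(phases)
        all_transitions.append(transitions)
    _write_csv(pd.DataFrame(traj_rows), out / "trajectories.csv")
    _write_csv(pd.DataFrame(seg_rows), out / "segments.csv")

    flat = [s for mt in all_segments for s in mt]
    growth = dyn.weighted_speed(flat, "growth")
    cat, res = dyn.event_frequencies(all_segments, all_transitions)
    summary["dynamics"] = {
        "n_microtubules": n_mt,
        "growth_speed_um_min": growth.weighted_mean,
        "growth_speed_se": growth.weighted_se,
        "n_growth_events": growth.n_events,
        "catastrophe_frequency_s": cat.frequency,
        "catastrophe_error_s": cat.error,
        "n_catastrophes": cat.n_events,
        "rescue_frequency_s": res.frequency,
        "rescue_error_s": res.error,
        "n_rescues": res.n_events,
    }
    try:
        shrink = dyn.weighted_speed(flat, "shrink")
        summary["dynamics"]["shrink_speed_um_min"] = shrink.weighted_mean
        summary["dynamics"]["shrink_speed_se"] = shrink.weighted_se
    except ValueError:
        warnings_log.append("dynamics: no shrink events in ensemble")

    # --- stage 2: rendered kymograph of the first microtubule --------------
    ocfg = config.get("optics", {})
    optics = simkit.OpticsParams(**ocfg)
    truth = simkit.GroundTruth(trajectory=first_traj)
    kymo = simkit.render_kymograph(truth, optics, channel="microtubule", rng_seed=seed + 7)
    tifffile.imwrite(out / "kymograph_mt.tif", kymo.data.astype(np.float32))

    # --- stage 3: FRAP traces and k_off comparison -------------------------
    fcfg = config.get("frap", {})
    n_traces = int(fcfg.get("n_traces_per_condition", 100))
    noise = float(fcfg.get("noise_sigma", 0.05))
    conditions = fcfg.get("conditions", {"gmpcpp": 0.26, "gdp": 1.07})
    fits_rows = []
    fits_by_cond: dict[str, list] = {}
    for ci, (cond, k_true) in enumerate(sorted(conditions.items())):
        fits_by_cond[cond] = []
        for r in range(n_traces):
            trace = simkit.simulate_frap_trace(
                float(k_true), plateau=float(fcfg.get("plateau", 0.8)),
                n_prebleach=int(fcfg.get("n_prebleach", 55)),
                frame_interval=float(fcfg.get("frame_interval", 0.2)),
                noise_sigma=noise, rng_seed=seed * 9001 + ci * 10007 + r,
                n_postbleach=int(fcfg.get("n_postbleach", 150)),
                roi_id=f"{cond}_{r:03d}", condition=cond,
            )
            fit = frapkit.fit_koff(frapkit.normalize_frap(trace))
            fits_by_cond[cond].append(fit)
            fits_rows.append(
                {"roi_id": trace.roi_id, "condition": cond, "A": fit.A,
                 "k_off_s": fit.k_off, "r_squared": fit.r_squared, "converged": fit.converged}
            )
    _write_csv(pd.DataFrame(fits_rows), out / "frap_fits.csv")
    summary["frap"] = frapkit.summarize_koff(fits_by_cond)

    # --- stage 4: crosslink events and classification ----------------------
    ecfg = config.get("events", {})
    per_class = int(ecfg.get("n_per_class", 10))
    ev_frame = float(ecfg.get("frame_interval", 2.0))
    spec_rows = []
    for label in ("bind_unbind", "sliding", "tip_tracking", "bundling"):
        spec_rows += [{"label": label} for _ in range(per_class)]
    ev_params = simkit.DynamicsParams(duration=float(ecfg.get("duration", 400.0)),
                                      rng_seed=seed + 31)
    mt_traj, _, _ = simkit.simulate_dynamic_instability(ev_params)
    tracks, records = simkit.simulate_crosslink_events(
        spec_rows, mt_traj, frame_interval=ev_frame, rng_seed=seed + 57
    )
    actin = {t.track_id.rsplit("_", 1)[0]: t for t in tracks if t.channel == "actin"}
    anillin = {t.track_id.rsplit("_", 1)[0]: t for t in tracks if t.channel == "anillin"}
    n_correct = 0
    event_rows = []
    for rec in records:
        result = ev.classify_event(actin[rec.event_id], mt_traj, anillin.get(rec.event_id))
        ok = result is not None and result.label == rec.label
        n_correct += int(ok)
        event_rows.append(
            {"event_id": rec.event_id, "true_label": rec.label,
             "predicted_label": result.label if result is not None else "rejected",
             "t_on_s": rec.t_on, "t_off_s": rec.t_off,
             "residence_time_s": rec.residence_time, "location": rec.location}
        )
    _write_csv(pd.DataFrame(event_rows), out / "events.csv")
    summary["events"] = {
        "n_events": len(records),
        "n_correctly_classified": n_correct,
        "accuracy": n_correct / len(records) if records else float("nan"),
    }

    # --- manifest -----------------------------------------------------------
    summary["warnings"] = warnings_log
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    summary["elapsed_s"] = round(time.time() - t_start, 3)  # not persisted: timing is not part of the determinism contract
    manifest = {
        "config": config,
        "seed": seed,
        "outputs": {
            p.name: _checksum(p) for p in sorted(out.glob("*.csv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
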