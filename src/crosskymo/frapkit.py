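"""FRAP normalization, single-exponential off-rate fitting and comparison.

The recovery of a reaction-limited binder after photobleaching follows

    y(t) = A (1 − exp(−t · k_off))

where y is the normalized fluorescence, A the (possibly incomplete) recovery
plateau and k_off the binder's unbinding rate. Traces are normalized by
subtracting the post-bleach minimum and dividing by the pre-bleach mean, so
the post-bleach minimum maps exactly to 0 and time is re-zeroed there,
consistent with the model having no offset term. Off-rate distributions are
asymmetric, so conditions are summarized by their median k_off and compared
with a Mann–Whitney U test.
"""
from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import FrapFit, FrapTrace
from .workbench import mann_whitney_u

__all__ = ["normalize_frap", "fit_koff", "summarize_koff", "recovery_model"]

K_BOUNDS = (1e-4, 1e2)  # s⁻¹
A_BOUNDS = (1e-9, 2.0)


def recovery_model(t: np.ndarray, A: float, k_off: float) -> np.ndarray:
    return A * (1.0 - np.exp(-t * k_off))


def normalize_frap(trace: FrapTrace) -> FrapTrace:
    """Normalize a FRAP trace to [post-bleach min → 0, pre-bleach mean → 1].

    normalized(t) = (I(t) − min_{t ≥ bleach} I) / mean_{t < bleach} I.
    Time is re-zeroed at the frame of the post-bleach minimum and
    ``bleach_index`` updated to point at it.
    """
    pre = trace.intensities[: trace.bleach_index]
    post = trace.intensities[trace.bleach_index :]
    pre_mean = float(pre.mean())
    if pre_mean == 0:
        raise ValueError("pre-bleach mean intensity is zero; cannot normalize")
    min_post = float(post.min())
    i_min = trace.bleach_index + int(np.argmin(post))
    norm = (trace.intensities - min_post) / pre_mean
    times = trace.times - trace.times[i_min]
    return FrapTrace(times, norm, bleach_index=i_min, roi_id=trace.roi_id, condition=trace.condition)


def fit_koff(trace: FrapTrace, min_post_points: int = 5) -> FrapFit:
    """Least-squares fit of A(1 − e^(−t·k_off)) to the post-bleach recovery.

    The fit uses only points from the (re-zeroed) bleach time onward.
    Initial values: A₀ = mean of the last 10% of points, k₀ = ln2 / time to
    half of A₀; bounds A ∈ (0, 2], k_off ∈ [1e−4, 1e2] s⁻¹. R² is computed
    on the fitted points; non-convergence is reported, not raised.
    """
    t = trace.times[trace.bleach_index :]
    y = trace.intensities[trace.bleach_index :]
    n = t.size
    if n < min_post_points:
        raise ValueError(f"need at least {min_post_points} post-bleach points, got {n}")

    n_tail = max(int(round(0.1 * n)), 1)
    a0 = float(np.clip(y[-n_tail:].mean(), A_BOUNDS[0] * 10, A_BOUNDS[1]))
    half_idx = np.nonzero(y >= a0 / 2.0)[0]
    t_half = t[half_idx[0]] if half_idx.size and t[half_idx[0]] > 0 else (t[-1] / 2.0 or 1.0)
    k0 = float(np.clip(math.log(2.0) / t_half, *K_BOUNDS))

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                recovery_model, t, y, p0=[a0, k0],
                bounds=([A_BOUNDS[0], K_BOUNDS[0]], [A_BOUNDS[1], K_BOUNDS[1]]),
                maxfev=10000,
            )
        if not np.all(np.isfinite(pcov)):
            converged = False
        a_fit, k_fit = float(popt[0]), float(popt[1])
        # a solution pinned at the k bounds is not a real convergence
        if math.isclose(k_fit, K_BOUNDS[0]) or math.isclose(k_fit, K_BOUNDS[1]):
            converged = False
    except RuntimeError:
        a_fit, k_fit = a0, k0
        converged = False

    resid = y - recovery_model(t, a_fit, k_fit)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("nan"))
    return FrapFit(a_fit, k_fit, r2, converged, n)


def summarize_koff(fits: Mapping[str, Sequence[FrapFit]]) -> dict:
    """Per-condition median k_off and pairwise Mann–Whitney comparisons.

    Fits with ``converged=False`` or negative R² are excluded from the
    medians (and counted). Empty conditions are flagged.
    """
    report: dict = {"conditions": {}, "tests": []}
    usable: dict[str, np.ndarray] = {}
    for cond, flist in fits.items():
        good = [f.k_off for f in flist if f.converged and f.r_squared >= 0]
        entry = {
            "n_total": len(flist),
            "n_used": len(good),
            "n_excluded": len(flist) - len(good),
        }
        if good:
            entry["median_k_off_s"] = float(np.median(good))
            usable[cond] = np.asarray(good)
        else:
            entry["flag"] = "no converged fits"
        report["conditions"][cond] = entry
    names = sorted(usable)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = mann_whitney_u(usable[names[i]], usable[names[j]])
            report["tests"].append(
                {"pair": [names[i], names[j]], "U": res.statistic,
                 "p_two_sided": res.p_two_sided, "method": res.method}
            )
    return report
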