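"""Coincidence-window estimation and paired comparison.

The window is quantified as 2σ of a zero-centred Gaussian
P(Δt) = A·exp(−Δt²/(2σ²)) least-squares fitted to the mean spike-probability
profile.  Per-cell (per-seed) σ values are the statistical units for the
paired t test between pharmacological conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .protocol import SpikeProbProfile


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class WindowEstimate:
    amplitude: float
    sigma: float          # ms
    rss: float
    converged: bool
    baseline: float = 0.0

    @property
    def window(self) -> float:
        """Coincidence window = 2σ (ms)."""
        return 2.0 * self.sigma


@dataclass(frozen=True)
class PairedWindowComparison:
    mean_difference: float
    t: float
    df: int
    p: float
    n_pairs: int


def fit_gaussian(profile: SpikeProbProfile, free_center: bool = False,
                 baseline: bool = True) -> WindowEstimate:
    """Fit P(Δt) = b + A·exp(−Δt²/(2σ²)) to the per-offset mean probabilities.

    The centre is fixed at Δt = 0 (the window is a width, not a latency) unless
    ``free_center``.  Unweighted least squares.  The non-negative floor ``b``
    absorbs offset-independent background spiking: with Bernoulli-activated
    synapse groups an occasional single-group draw exceeds spike threshold at
    any offset, so the profile sits on a pedestal and the coincidence window is
    the width of the bump above it (``baseline=False`` forces b = 0).

    An all-zero profile raises :class:`DegenerateFitError`; a flat or otherwise
    ill-conditioned profile is returned with ``converged=False`` rather than
    silently.
    """
    x = np.asarray(profile.offsets, dtype=float)
    y = np.asarray(profile.spike_probability, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 offsets to fit a window")
    if not np.any(y > 0):
        raise DegenerateFitError("all-zero spike-probability profile")

    span = x.max() - x.min()
    if np.ptp(y) < 1e-12:  # flat profile: sigma unidentifiable
        return WindowEstimate(float(y[0]), np.inf, 0.0, False, float(y[0]))

    a0 = float(np.ptp(y)) if baseline else float(y.max())
    b0 = float(y.min()) if baseline else 0.0
    s0 = max(span / 6, 1.0)
    smax = 5 * span

    def f(x, a, s, b=0.0, mu=0.0):
        return b + a * np.exp(-((x - mu) ** 2) / (2 * s**2))

    names = ["a", "s"] + (["b"] if baseline else []) + (["mu"] if free_center else [])
    p0 = {"a": a0, "s": s0, "b": b0, "mu": 0.0}
    lo = {"a": 0.0, "s": 1e-6, "b": 0.0, "mu": x.min()}
    hi = {"a": 1.5, "s": 10 * span, "b": 1.0, "mu": x.max()}

    def wrapped(x, *p):
        kw = dict(zip(names, p))
        return f(x, **kw)

    try:
        popt, _ = optimize.curve_fit(
            wrapped, x, y, p0=[p0[k] for k in names],
            bounds=([lo[k] for k in names], [hi[k] for k in names]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError:
        return WindowEstimate(a0, np.inf, float(np.sum((y - y.mean()) ** 2)),
                              False, b0)

    fit = dict(zip(names, popt))
    a, s = float(fit["a"]), abs(float(fit["s"]))
    b = float(fit.get("b", 0.0))
    rss = float(np.sum((wrapped(x, *popt) - y) ** 2))
    # A sigma beyond the sampled range, or a vanishing bump, is not a
    # measurement of the window.
    converged = bool(np.isfinite(s) and 0 < s < smax and a > 0.05)
    return WindowEstimate(a, s, rss, converged, b)


def paired_window_test(sigmas_a, sigmas_b) -> PairedWindowComparison:
    """Classical paired t test on per-cell σ values (two-sided)."""
    a = np.asarray(sigmas_a, dtype=float)
    b = np.asarray(sigmas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(a, b)
    return PairedWindowComparison(
        mean_difference=float(d.mean()),
        t=float(res.statistic),
        df=len(a) - 1,
        p=float(res.pvalue),
        n_pairs=len(a),
    )


def summarize_windows(estimates) -> tuple[float, float]:
    """Mean and sample SD of the 2σ windows (ms); SD = 0 for one estimate."""
    w = np.asarray([e.window for e in estimates], dtype=float)
    if len(w) == 0:
        raise ValueError("no estimates")
    sd = float(w.std(ddof=1)) if len(w) > 1 else 0.0
    return float(w.mean()), sd
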