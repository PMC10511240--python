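"""Decay/relocation kinetics and inference of the repressive 5-IP7 threshold.

The argument formalized here: in cells with a strongly exaggerated 5-IP7
pool, the pool decays roughly exponentially after Pi withdrawal while the
PHO-pathway readout (nuclear Pho4, I_N/I_C) follows a delayed sigmoid.  The
concentration at which the pathway de-represses is the fitted decay curve
evaluated at the relocation half-maximum time:

    threshold = C0 * exp(-k * t_half)

Alternative anchors (e.g. 5% onset of the logistic) are exposed as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit",
    "LogisticFit",
    "ThresholdEstimate",
    "fit_exponential_decay",
    "fit_logistic",
    "infer_threshold",
]


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential fit C(t) = C0 exp(-k t)."""

    c0: float
    k: float
    sse: float
    method: str = "log-linear init + nonlinear least squares"

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("C0 must be positive")
        if self.k < 0:
            raise ValueError("decay rate must be >= 0")

    def concentration(self, t) -> np.ndarray:
        return self.c0 * np.exp(-self.k * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class LogisticFit:
    """Four-parameter logistic: baseline + amplitude / (1 + exp(-(t - t_half)/width))."""

    baseline: float
    amplitude: float
    t_half: float
    width: float
    sse: float
    flat: bool = False  # flagged "no transition"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.t_half < 0:
            raise ValueError("t_half must be >= 0")

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.baseline + self.amplitude / (1.0 + np.exp(-(t - self.t_half) / self.width))


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_um: float
    t_anchor_min: float
    decay: DecayFit
    anchor: str = "t_half"

    def __post_init__(self) -> None:
        if self.threshold_um > self.decay.c0 * (1 + 1e-12):
            raise ValueError("threshold cannot exceed the fitted C0")


def _logistic(t, baseline, amplitude, t_half, width):
    return baseline + amplitude / (1.0 + np.exp(-(t - t_half) / width))


def fit_exponential_decay(times, concentrations) -> DecayFit:
    """Least-squares fit of C0 exp(-k t), initialized from log-linear regression.

    Non-positive concentrations are treated as below detection: they are
    excluded from the log-space initialization but kept in the nonlinear
    refinement (as zeros they still pull the tail down).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    keep = np.isfinite(t) & np.isfinite(c)
    t, c = t[keep], c[keep]
    if t.size < 3:
        raise ValueError("need at least 3 usable points")
    if np.unique(t).size != t.size:
        raise ValueError("times must be distinct")
    if np.all(c <= 0):
        raise ValueError("all concentrations are zero or below detection")

    pos = c > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(c[pos]), 1)
        c0_init, k_init = float(np.exp(intercept)), float(max(-slope, 0.0))
    else:
        c0_init, k_init = float(c[pos][0]), 0.01

    popt, _ = curve_fit(
        lambda tt, c0, k: c0 * np.exp(-k * tt),
        t,
        c,
        p0=[max(c0_init, 1e-12), k_init],
        bounds=([1e-12, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    c0, k = map(float, popt)
    sse = float(np.sum((c - c0 * np.exp(-k * t)) ** 2))
    return DecayFit(c0=c0, k=k, sse=sse)


def fit_logistic(
    times,
    ratios,
    n_restarts: int = 5,
    seed: int = 0,
    flat_rel_amplitude: float = 0.02,
) -> LogisticFit:
    """Bounded least-squares fit of the 4-parameter logistic.

    Bounds: amplitude >= 0, t_half within the observed time range,
    width > 0.  On convergence failure the initial guess is jittered up to
    ``n_restarts`` times (seeded); persistent failure raises.  A fit whose
    amplitude is below ``flat_rel_amplitude`` of the data range (or whose
    data are constant) is flagged ``flat`` ("no transition").
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    keep = np.isfinite(t) & np.isfinite(r)
    t, r = t[keep], r[keep]
    if t.size < 5:
        raise ValueError("need at least 5 points")

    span = float(np.ptp(r))
    if span == 0.0:
        return LogisticFit(baseline=float(r[0]), amplitude=0.0,
                           t_half=float(t.min()), width=1.0, sse=0.0, flat=True)

    half = r.min() + span / 2.0
    above = t[r >= half]
    t_half0 = float(above.min()) if above.size else float(np.median(t))
    p0 = [float(r.min()), span, t_half0, max(float(np.ptp(t)) / 10.0, 1.0)]
    lo = [-np.inf, 0.0, float(t.min()), 1e-6]
    hi = [np.inf, np.inf, float(t.max()), np.inf]

    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        guess = list(p0)
        if attempt > 0:
            guess[2] = float(rng.uniform(t.min(), t.max()))
            guess[3] = float(rng.uniform(0.02, 0.5) * max(np.ptp(t), 1.0))
        try:
            popt, _ = curve_fit(_logistic, t, r, p0=guess, bounds=(lo, hi), maxfev=20000)
            break
        except RuntimeError as err:  # pragma: no cover - needs pathological data
            last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"logistic fit failed after {n_restarts} restarts") from last_err

    baseline, amplitude, t_half, width = map(float, popt)
    sse = float(np.sum((r - _logistic(t, *popt)) ** 2))
    flat = amplitude < flat_rel_amplitude * span
    return LogisticFit(baseline=baseline, amplitude=amplitude, t_half=max(t_half, 0.0),
                       width=width, sse=sse, flat=flat)


def infer_threshold(
    decay_fit: DecayFit,
    logistic_fit: LogisticFit,
    anchor: str = "t_half",
    onset_fraction: float = 0.05,
) -> ThresholdEstimate:
    """Concentration of the fitted decay at the relocation anchor time.

    ``anchor='t_half'`` uses the logistic half-maximum;
    ``anchor='onset'`` uses the time at which the logistic has risen by
    ``onset_fraction`` of its amplitude.
    """
    if logistic_fit.flat:
        raise ValueError("relocation series is flat: no transition to anchor the threshold")
    if anchor == "t_half":
        t_anchor = logistic_fit.t_half
    elif anchor == "onset":
        if not 0.0 < onset_fraction < 0.5:
            raise ValueError("onset fraction must be in (0, 0.5)")
        t_anchor = logistic_fit.t_half + logistic_fit.width * float(
            np.log(onset_fraction / (1.0 - onset_fraction))
        )
        t_anchor = max(t_anchor, 0.0)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    threshold = float(decay_fit.concentration(t_anchor))
    return ThresholdEstimate(threshold_um=threshold, t_anchor_min=float(t_anchor),
                             decay=decay_fit, anchor=anchor)
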