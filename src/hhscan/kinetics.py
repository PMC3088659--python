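"""Self-cleavage kinetics: kobs estimation, biphasic fits, fold changes.

Two rate models are supported, both in units of min⁻¹:

* monophasic pseudo-first-order cleavage, ``F(t) = A (1 - exp(-kobs t))``.
  kobs is estimated the classical way, as minus the slope of the
  least-squares line of ln(fraction precursor remaining) versus time,
  restricted to the early part of the reaction (by default the first 5-30%
  of the amplitude, where the ln-linear approximation is safest);
* biphasic cleavage, ``F(t) = a (1 - exp(-b t)) + c (1 - exp(-d t))``,
  fitted by bounded non-linear least squares with deterministic multistart
  initialization; ``b`` is reported as the larger rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .model import KineticsTrace

DEFAULT_WINDOW = (0.05, 0.30)


class FitError(RuntimeError):
    """Raised when a kinetics fit cannot be performed or did not converge."""


@dataclass
class KineticsFit:
    """A fitted rate model for one cleavage time course.

    For a monophasic fit only ``kobs`` is set; for a biphasic fit the four
    parameters of ``F = a(1-e^{-bt}) + c(1-e^{-dt})`` are set with ``b >= d``
    by relabeling.  Rates are min⁻¹; amplitudes are fractions cleaved.
    """

    model: str                                # "monophasic" | "biphasic"
    kobs: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None
    d: Optional[float] = None
    rss: float = float("nan")
    n_points: int = 0
    window: Optional[Tuple[float, float]] = None
    points_used: Sequence[int] = field(default_factory=list)

    def __post_init__(self):
        for rate in (self.kobs, self.b, self.d):
            if rate is not None and rate <= 0:
                raise ValueError("rate constants must be positive")
        if self.model == "biphasic":
            if self.b is not None and self.d is not None and self.b < self.d:
                raise ValueError("biphasic convention requires b >= d")
            for amp in (self.a, self.c):
                if amp is not None and not (0.0 <= amp <= 1.05):
                    raise ValueError("amplitudes must lie in [0, 1.05]")
            if self.a is not None and self.c is not None and self.a + self.c > 1.05:
                raise ValueError("total amplitude exceeds 1 beyond fit slack")

    def rate_constants(self) -> Tuple[float, ...]:
        if self.model == "monophasic":
            return (self.kobs,)
        return (self.b, self.d)

    def summary(self) -> str:
        lines = [f"kinetics fit: {self.model} ({self.n_points} points)"]
        if self.model == "monophasic":
            lines.append(f"  kobs = {self.kobs:.4g} min^-1")
            if self.window:
                lines.append(
                    f"  window = {self.window[0]:.0%}-{self.window[1]:.0%} of reaction"
                    f" ({len(list(self.points_used))} points used)"
                )
        else:
            lines.append(f"  a = {self.a:.4g}   b = {self.b:.4g} min^-1  (fast phase)")
            lines.append(f"  c = {self.c:.4g}   d = {self.d:.4g} min^-1  (slow phase)")
        lines.append(f"  residual sum of squares = {self.rss:.4g}")
        return "\n".join(lines)


def monophasic_curve(t, kobs: float, amplitude: float = 1.0):
    return amplitude * (1.0 - np.exp(-kobs * np.asarray(t, dtype=float)))


def biphasic_curve(t, a: float, b: float, c: float, d: float):
    t = np.asarray(t, dtype=float)
    return a * (1.0 - np.exp(-b * t)) + c * (1.0 - np.exp(-d * t))


def simulate_trace(
    times: Sequence[float],
    kobs: Optional[float] = None,
    amplitude: float = 1.0,
    biphasic: Optional[Tuple[float, float, float, float]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> KineticsTrace:
    """Simulate a cleavage time course with Gaussian noise, clipped to [0, 1].

    Provide either ``kobs`` (monophasic) or ``biphasic=(a, b, c, d)``.
    Deterministic for a fixed seed; the noiseless limit reproduces the model
    exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if (kobs is None) == (biphasic is None):
        raise ValueError("provide exactly one of kobs or biphasic parameters")
    if kobs is not None:
        if kobs <= 0:
            raise ValueError("kobs must be positive")
        f = monophasic_curve(times, kobs, amplitude)
    else:
        a, b, c, d = biphasic
        if b <= 0 or d <= 0:
            raise ValueError("rate constants must be positive")
        f = biphasic_curve(times, a, b, c, d)
    if noise_sd:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=len(f))
    f = np.clip(f, 0.0, 1.0)
    return KineticsTrace(times=list(times), fraction_cleaved=[float(x) for x in f])


def fit_kobs_linear(
    trace: KineticsTrace,
    window: Tuple[float, float] = DEFAULT_WINDOW,
    endpoint: float | str = 1.0,
) -> KineticsFit:
    """kobs from the ln-linear early phase of a time course.

    Restricts to points whose fraction cleaved lies within ``window``
    (default the first 5-30%) of the reaction endpoint, then fits
    ln(fraction remaining) versus time by least squares; kobs is minus the
    slope.  ``endpoint`` is the reaction amplitude: 1.0 for a reaction that
    goes to completion, a float for a known plateau, or ``"observed"`` to
    use the largest observed fraction.
    """
    t = np.asarray(trace.times, dtype=float)
    f = np.asarray(trace.fraction_cleaved, dtype=float)
    if endpoint == "observed":
        amp = float(f.max())
        if amp <= 0:
            raise FitError("no reaction progress: all fractions are zero")
    else:
        amp = float(endpoint)
        if amp <= 0:
            raise FitError("endpoint must be positive")
    lo, hi = window
    rel = f / amp
    mask = (rel >= lo) & (rel <= hi)
    if int(mask.sum()) < 2:
        raise FitError(
            "fewer than 2 points fall in the "
            f"{lo:.0%}-{hi:.0%} window; consider a full-range or biphasic fit"
        )
    if np.any(rel[mask] >= 1.0):
        raise FitError("fraction cleaved reaches the endpoint inside the fit window")
    y = np.log(1.0 - rel[mask])
    res = stats.linregress(t[mask], y)
    kobs = -float(res.slope)
    if kobs <= 0:
        raise FitError("non-positive rate estimate: no forward reaction progress")
    fitted = amp * (1.0 - np.exp(-kobs * t[mask]))
    return KineticsFit(
        model="monophasic",
        kobs=kobs,
        rss=float(np.sum((f[mask] - fitted) ** 2)),
        n_points=len(t),
        window=window,
        points_used=list(np.flatnonzero(mask)),
    )


def fit_biphasic(
    trace: KineticsTrace,
    n_starts: int = 10,
    seed: int = 0,
) -> KineticsFit:
    """Fit the two-phase model F = a(1-e^{-bt}) + c(1-e^{-dt}).

    Uses bounded non-linear least squares with ``n_starts`` deterministic
    multistart initializations (amplitudes from the early/late plateaus, the
    slow rate initialized at b/20).  The fast phase is labelled ``b`` by
    convention.  Raises :class:`FitError` on non-convergence.
    """
    t = np.asarray(trace.times, dtype=float)
    f = np.asarray(trace.fraction_cleaved, dtype=float)
    if len(t) < 6:
        raise FitError("a biphasic fit needs at least 6 points")
    slope_all = stats.linregress(t, f).slope
    if slope_all < 0 and f[0] > f[-1]:
        raise FitError("fraction cleaved decreases over the trace; not a cleavage time course")

    fmax = float(f.max())
    if fmax <= 0:
        raise FitError("no reaction progress: all fractions are zero")
    t_scale = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
    b0_base = max(1.0 / t_scale, 1e-3)
    a0 = 0.7 * fmax
    c0 = max(fmax - a0, 0.05)

    rng = np.random.default_rng(seed)
    bounds = ([0.0, 1e-9, 0.0, 1e-10], [1.05, 1e4, 1.05, 1e4])
    best = None
    for i in range(n_starts):
        if i == 0:
            p0 = [a0, b0_base, c0, b0_base / 20.0]
        else:
            jitter = rng.lognormal(mean=0.0, sigma=1.0, size=4)
            p0 = [
                min(a0 * jitter[0], 1.0),
                b0_base * jitter[1],
                min(c0 * jitter[2], 1.0),
                b0_base / 20.0 * jitter[3],
            ]
        try:
            popt, _ = optimize.curve_fit(
                biphasic_curve, t, f, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((biphasic_curve(t, *popt) - f) ** 2))
        if popt[0] + popt[2] > 1.05:
            continue
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError(
            f"biphasic fit failed to converge after {n_starts} starts "
            f"(n={len(t)}, fmax={fmax:.3g})"
        )
    rss, (a, b, c, d) = best
    if d > b:
        a, b, c, d = c, d, a, b
    b = max(b, 1e-12)
    d = max(d, 1e-12)
    return KineticsFit(
        model="biphasic", a=float(a), b=float(b), c=float(c), d=float(d),
        rss=rss, n_points=len(t),
    )


def fold_change(k_fast: float, k_slow: float) -> float:
    """Ratio of two rate constants (report to 3 significant figures).

    The exact ratio is returned so that fold_change(x, y) * fold_change(y, x)
    is exactly 1; use :func:`format_fold_change` for display.
    """
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("rate constants must be positive")
    return k_fast / k_slow


def format_fold_change(ratio: float) -> str:
    """Format a rate ratio to 3 significant figures, e.g. '425'."""
    return f"{float(f'{ratio:.3g}'):g}"
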