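"""Exponential-phase analysis of stopped-flow fluorescence transients.

Mixing a FRET-labelled back-folded tail with excess partner produces a
biphasic trace: a concentration-dependent rise (partner binding) followed
by a partial, concentration-independent fall (unfolding).  Each phase is
fitted separately to a single exponential, and the observed rates are
regressed on partner concentration:

    k_obs = k_on [P] + k_off          (binding phase: linear)
    k_obs = const                     (unfolding phase: independent)

so the slope of the straight line is the association rate constant, the
intercept the dissociation rate constant, and their ratio a kinetically
determined Kd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

__all__ = [
    "FluorescenceTrace",
    "ExpFit",
    "RateLaw",
    "FitError",
    "fit_single_exponential",
    "split_biphasic",
    "analyze_biphasic",
    "kobs_regression",
]

#: Instrument dead time (s): no signal is observable before this after mixing.
DEFAULT_DEAD_TIME = 0.002


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the initial guesses that were used."""

    def __init__(self, message: str, guesses: Optional[dict] = None):
        super().__init__(message)
        self.guesses = guesses or {}


@dataclass
class FluorescenceTrace:
    """A single-channel stopped-flow record."""

    time: np.ndarray
    signal: np.ndarray
    probe: str = ""
    partner_conc: float = float("nan")
    dead_time: float = DEFAULT_DEAD_TIME

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have identical shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.count_nonzero(self.time >= self.dead_time) < 20:
            raise ValueError("need at least 20 points after dead-time exclusion")

    def after_dead_time(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.time >= self.dead_time
        return self.time[m], self.signal[m]


@dataclass
class ExpFit:
    """Result of a single-exponential phase fit: y = offset + A(1 - e^{-kt'})."""

    k_obs: float
    amplitude: float
    offset: float
    k_obs_err: float = float("nan")
    window: tuple[float, float] = (float("nan"), float("nan"))
    rms: float = float("nan")
    short_window: bool = False  # window shorter than 3/k_obs


@dataclass
class RateLaw:
    """Linear dependence of k_obs on ligand concentration."""

    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    Kd: float = float("nan")
    Kd_err: float = float("nan")
    independence_flag: bool = False
    mean_kobs: float = float("nan")


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values from the endpoints and a log-linear fit."""
    y0, yend = y[0], y[-1]
    amp0 = yend - y0
    resid = np.abs(yend - y)
    mask = resid > 0.05 * max(abs(amp0), 1e-30)
    if mask.sum() >= 3 and abs(amp0) > 0:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-9)
    return k0, amp0, y0


def fit_single_exponential(
    trace: FluorescenceTrace,
    window: Optional[tuple[float, float]] = None,
    direction: str = "rise",
) -> ExpFit:
    """Fit ``y = offset + amplitude (1 - exp(-k_obs t'))`` on a time window.

    ``t'`` is measured from the window start.  The window defaults to the
    full post-dead-time trace.  ``direction`` ("rise" or "fall") fixes the
    expected amplitude sign; a fitted amplitude of the wrong sign or a
    degenerate (flat) trace raises :class:`FitError`.
    """
    if direction not in ("rise", "fall"):
        raise ValueError("direction must be 'rise' or 'fall'")
    t_all, y_all = trace.after_dead_time()
    if window is None:
        window = (t_all[0], t_all[-1])
    lo, hi = window
    m = (t_all >= lo) & (t_all <= hi)
    t, y = t_all[m], y_all[m]
    if len(t) < 10:
        raise ValueError("window must contain at least 10 points after dead time")
    tp = t - t[0]

    k0, amp0, off0 = _initial_guesses(tp, y)
    guesses = {"k_obs": k0, "amplitude": amp0, "offset": off0}
    span = float(np.ptp(y))
    if span == 0 or abs(amp0) < 1e-12 * max(abs(off0), 1.0):
        raise FitError("degenerate (zero-amplitude) trace", guesses)

    def model(tt, k, a, c):
        return c + a * (1.0 - np.exp(-k * tt))

    try:
        popt, pcov = curve_fit(
            model, tp, y, p0=[k0, amp0, off0], maxfev=10000,
            bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message path
        raise FitError(f"exponential fit did not converge: {exc}", guesses) from exc

    k, a, c = popt
    if direction == "rise" and a <= 0:
        raise FitError("rise fit returned non-positive amplitude", guesses)
    if direction == "fall" and a >= 0:
        raise FitError("fall fit returned non-negative amplitude", guesses)
    resid = y - model(tp, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    # realized signal change over the window; a degenerate fit can hide a
    # noise-sized change behind a tiny rate with a huge nominal amplitude
    realized = abs(a) * (1.0 - np.exp(-k * (tp[-1] - tp[0])))
    if realized < 2.0 * rms:
        raise FitError("amplitude indistinguishable from noise", guesses)
    return ExpFit(
        k_obs=float(k),
        amplitude=float(a),
        offset=float(c),
        k_obs_err=float(np.sqrt(pcov[0, 0])),
        window=(float(t[0]), float(t[-1])),
        rms=rms,
        short_window=(t[-1] - t[0]) < 3.0 / k,
    )


def split_biphasic(
    trace: FluorescenceTrace, smooth_width: int = 5
) -> tuple[tuple[float, float], Optional[tuple[float, float]]]:
    """Locate the turning point of a rise-then-fall trace.

    The peak is found on a moving-average smoothed copy of the signal.
    Returns ``(rise_window, fall_window)`` in seconds; ``fall_window`` is
    ``None`` when the trace is effectively monotone (peak in the last 2%
    of points, or no interior maximum).
    """
    t, y = trace.after_dead_time()
    kernel = np.ones(smooth_width) / smooth_width
    ys = np.convolve(y, kernel, mode="same")
    # exclude convolution edge artefacts from the peak search
    half = smooth_width // 2
    core = slice(half, len(ys) - half if len(ys) > 2 * half else None)
    ipk = int(np.argmax(ys[core])) + half
    t_peak = t[ipk]
    if ipk >= len(t) - max(2, len(t) // 50):
        return (t[0], t[-1]), None
    return (t[0], t_peak), (t_peak, t[-1])


def _fitted_curve(fit: ExpFit, t: np.ndarray) -> np.ndarray:
    """Evaluate a fitted exponential at absolute times (extrapolates freely)."""
    return fit.offset + fit.amplitude * (1.0 - np.exp(-fit.k_obs * (t - fit.window[0])))


def analyze_biphasic(
    trace: FluorescenceTrace, n_iter: int = 3
) -> tuple[ExpFit, Optional[ExpFit]]:
    """Phase-separated fits of a rise-then-fall trace with mutual correction.

    Each phase is fitted on its own window — the rise on
    [dead_time, t_peak], the fall from three fast-phase time constants
    past the peak — but, because the early tail of the slow phase leaks
    into the rise window (and vice versa), the currently fitted
    counterpart exponential is subtracted from the trace before each
    phase fit and the pair is iterated.  Both exponentials belong to the
    same model family, so on a clean two-exponential trace this
    coordinate iteration converges to the exact decomposition while each
    phase is still analysed separately over its own time scale.

    Returns ``(rise_fit, fall_fit)``; ``fall_fit`` is ``None`` for a
    monotone trace (single-phase result).
    """
    rise_win, fall_win = split_biphasic(trace)
    rise = fit_single_exponential(trace, window=rise_win, direction="rise")
    if fall_win is None:
        return rise, None
    t, y = trace.time, trace.signal
    t_peak = fall_win[0]
    fall: Optional[ExpFit] = None
    for _ in range(n_iter):
        fall_start = t_peak + 3.0 / rise.k_obs
        if fall_start >= t[-1]:
            break
        minus_fast = FluorescenceTrace(
            t, y - _fitted_curve(rise, t) + rise.offset,
            trace.probe, trace.partner_conc, trace.dead_time,
        )
        fall = fit_single_exponential(
            minus_fast, window=(fall_start, t[-1]), direction="fall"
        )
        minus_slow = FluorescenceTrace(
            t, y - _fitted_curve(fall, t) + fall.offset,
            trace.probe, trace.partner_conc, trace.dead_time,
        )
        rise = fit_single_exponential(minus_slow, window=rise_win, direction="rise")
    return rise, fall


def kobs_regression(
    fits: pd.DataFrame | Sequence[tuple[float, float]],
    min_concentrations: int = 3,
    span_fraction: float = 0.10,
) -> RateLaw:
    """Regress observed rates on concentration to extract k_on and k_off.

    Parameters
    ----------
    fits : DataFrame with columns ``conc_uM`` and ``k_obs`` (one row per
        replicate fit), or a sequence of ``(conc, k_obs)`` pairs.

    Replicates are averaged at the k_obs level; the line is fitted to the
    per-concentration means by weighted least squares (weights = 1/SEM^2
    when every concentration has >= 2 replicates, unweighted otherwise).
    ``Kd = intercept / slope`` with its error propagated by the delta
    method.  The rate is flagged concentration-independent when the 95%
    confidence interval of the slope contains zero, or when the slope
    accounts for less than ``span_fraction`` of the mean k_obs across the
    concentration range.
    """
    if not isinstance(fits, pd.DataFrame):
        fits = pd.DataFrame(fits, columns=["conc_uM", "k_obs"])
    g = fits.groupby("conc_uM")["k_obs"]
    means = g.mean()
    counts = g.count()
    sems = g.sem()
    if len(means) < min_concentrations:
        raise ValueError(
            f"need >= {min_concentrations} distinct concentrations, got {len(means)}"
        )

    x = means.index.to_numpy(dtype=float)
    ym = means.to_numpy(dtype=float)
    if (counts >= 2).all() and np.all(np.nan_to_num(sems.to_numpy()) > 0):
        w = 1.0 / sems.to_numpy() ** 2
    else:
        w = np.ones_like(ym)

    # weighted straight-line fit with parameter covariance
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ ym)
    resid = ym - X @ beta
    dof = max(len(x) - 2, 1)
    s2 = (resid @ W @ resid) / dof
    cov = s2 * np.linalg.inv(xtwx)
    intercept, slope = beta
    intercept_err, slope_err = np.sqrt(np.diag(cov))

    tcrit = t_dist.ppf(0.975, dof)
    ci_contains_zero = abs(slope) <= tcrit * slope_err
    small_span = abs(slope) * x.max() < span_fraction * ym.mean()
    independent = bool(ci_contains_zero or small_span)

    law = RateLaw(
        slope=float(slope),
        intercept=float(intercept),
        slope_err=float(slope_err),
        intercept_err=float(intercept_err),
        independence_flag=independent,
        mean_kobs=float(ym.mean()),
    )
    if not independent and slope > 0:
        kd = intercept / slope
        # delta method; the off-diagonal covariance term matters
        var = (
            (intercept_err / slope) ** 2
            + (intercept * slope_err / slope**2) ** 2
            - 2 * intercept * cov[0, 1] / slope**3
        )
        law.Kd = float(kd)
        law.Kd_err = float(np.sqrt(max(var, 0.0)))
    return law
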