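"""Equilibrium FRET titrations of the back-folded myosin VI tail.

A fixed concentration of donor-labelled tail is titrated with
acceptor-labelled cargo-binding domain (or partner).  After subtracting
the direct-excitation background of the acceptor, the FRET intensity is
proportional to the donor-acceptor complex concentration, which at total
concentrations comparable to Kd follows the tight-binding (quadratic)
isotherm

    [C] = (S - sqrt(S^2 - 4 D A)) / 2,   S = D + A + Kd,

with D, A the *total* donor and acceptor concentrations.  Competition
experiments add a partner that sequesters the acceptor domain and
suppresses the apparent complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.optimize import brentq

__all__ = [
    "TitrationSeries",
    "QuadraticBindingParams",
    "complex_concentration",
    "correct_direct_excitation",
    "fit_titration",
    "simulate_competition",
]

KD_BOUNDS = (1e-3, 1e3)  # µM; a fit pinned at either bound is unidentifiable


@dataclass
class TitrationSeries:
    """One titration: acceptor grid vs FRET intensity at fixed donor."""

    donor_total: float
    acceptor_total: np.ndarray
    intensity: np.ndarray  # background-corrected FRET intensity
    raw_intensity: Optional[np.ndarray] = None
    replicate: int = 0

    def __post_init__(self) -> None:
        self.acceptor_total = np.asarray(self.acceptor_total, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.acceptor_total < 0):
            raise ValueError("acceptor concentrations must be nonnegative")
        if np.any(np.diff(self.acceptor_total) < 0):
            raise ValueError("acceptor grid must be increasing")


@dataclass
class QuadraticBindingParams:
    Kd: float
    signal_per_complex: float
    baseline: float
    Kd_err: float = float("nan")
    converged: bool = True
    flag: str = ""


def complex_concentration(donor_total, acceptor_total, Kd):
    """Quadratic-isotherm complex concentration (µM), vectorized.

    Uses the mass-balance root ``<= min(D, A)``, evaluated in the
    cancellation-free form ``2 D A / (S + sqrt(S^2 - 4 D A))`` so it is
    accurate for Kd both far below and far above the totals, and exactly
    continuous at Kd = 0 (stoichiometric limit min(D, A)).
    """
    D = np.asarray(donor_total, dtype=float)
    A = np.asarray(acceptor_total, dtype=float)
    if np.any(D < 0) or np.any(A < 0) or np.any(np.asarray(Kd) < 0):
        raise ValueError("concentrations and Kd must be nonnegative")
    S = D + A + Kd
    disc = np.sqrt(np.clip(S * S - 4.0 * D * A, 0.0, None))
    denom = S + disc
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, 2.0 * D * A / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def correct_direct_excitation(
    acceptor_total: np.ndarray,
    raw_intensity: np.ndarray,
    control_intensity: Optional[np.ndarray] = None,
    n_tail: int = 3,
) -> tuple[np.ndarray, dict]:
    """Subtract the acceptor direct-excitation background.

    With an acceptor-only control series, the background is its linear
    fit versus acceptor concentration.  Without one, the slope is
    estimated from the top ``n_tail`` acceptor points of the saturating
    titration itself (where the binding curve is flat and residual slope
    is attributable to direct excitation) and the result is flagged.
    """
    a = np.asarray(acceptor_total, dtype=float)
    y = np.asarray(raw_intensity, dtype=float)
    if control_intensity is not None:
        slope, inter = np.polyfit(a, np.asarray(control_intensity, float), 1)
        info = {"method": "control", "slope": float(slope)}
        return y - slope * a, info
    slope = np.polyfit(a[-n_tail:], y[-n_tail:], 1)[0]
    info = {"method": "tail_slope", "slope": float(slope), "flagged": True}
    return y - slope * a, info


def fit_titration(series: TitrationSeries, min_points: int = 6) -> QuadraticBindingParams:
    """Nonlinear least-squares fit of the quadratic binding isotherm.

    Model: ``intensity = baseline + signal_per_complex * [C](D, A; Kd)``.
    A fit whose Kd lands on the (1e-3, 1e3) µM bounds, or that fails to
    converge, is returned with ``converged=False`` and a reason flag.
    """
    A = series.acceptor_total
    y = series.intensity
    if len(A) < min_points:
        raise ValueError(f"need >= {min_points} acceptor points, got {len(A)}")
    if np.ptp(y) == 0:
        return QuadraticBindingParams(
            np.nan, 0.0, float(y[0]), converged=False, flag="flat series (zero signal)"
        )
    D = series.donor_total

    def model(a, Kd, s, c0):
        return c0 + s * complex_concentration(D, a, Kd)

    m = Model(model)
    params = m.make_params(
        Kd=dict(value=max(np.median(A), 2 * KD_BOUNDS[0]), min=KD_BOUNDS[0], max=KD_BOUNDS[1]),
        s=dict(value=(y[-1] - y[0]) / max(D, 1e-12)),
        c0=dict(value=float(y[0])),
    )
    res = m.fit(y, params, a=A)
    kd = float(res.params["Kd"].value)
    out = QuadraticBindingParams(
        Kd=kd,
        signal_per_complex=float(res.params["s"].value),
        baseline=float(res.params["c0"].value),
        Kd_err=float(res.params["Kd"].stderr or np.nan),
        converged=bool(res.success),
    )
    if not res.success:
        out.flag = "optimizer did not converge"
    elif kd <= KD_BOUNDS[0] * 1.01 or kd >= KD_BOUNDS[1] * 0.99:
        out.converged = False
        out.flag = "Kd at bounds (unidentifiable)"
    return out


def free_acceptor_competition(
    donor_total: float,
    acceptor_total: float,
    competitor_total: float,
    Kd_pair: float,
    Kd_competitor: float,
    xtol: float = 1e-14,
) -> float:
    """Free-acceptor concentration in the three-species competitive equilibrium.

    Solves the scalar mass balance
    ``A + D_t A/(A+Kd_p) + C_t A/(A+Kd_c) = A_t`` (monotone in A) by
    bracketed root finding.
    """
    At = float(acceptor_total)
    if At == 0:
        return 0.0

    def f(a):
        return (
            a
            + donor_total * a / (a + Kd_pair)
            + competitor_total * a / (a + Kd_competitor)
            - At
        )

    return brentq(f, 0.0, At, xtol=xtol, rtol=8.9e-16)


def simulate_competition(
    donor_total: float,
    acceptor_grid: Sequence[float],
    competitor_total: float,
    Kd_pair: float,
    Kd_competitor: float,
    signal_per_complex: float = 1.0,
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Predicted corrected-intensity curve under competitive sequestration.

    The acceptor partitions between the donor (Kd_pair) and a competitor
    that sequesters it (Kd_competitor).  At ``competitor_total = 0`` the
    donor-acceptor complex reduces exactly to the quadratic isotherm.
    Returns a DataFrame with acceptor_uM, complex_uM and intensity.
    """
    if donor_total < 0 or competitor_total < 0:
        raise ValueError("totals must be nonnegative")
    if Kd_pair <= 0 or Kd_competitor <= 0:
        raise ValueError("both Kd must be positive")
    grid = np.asarray(acceptor_grid, dtype=float)
    complexes = np.empty_like(grid)
    for i, At in enumerate(grid):
        a_free = free_acceptor_competition(
            donor_total, At, competitor_total, Kd_pair, Kd_competitor
        )
        complexes[i] = donor_total * a_free / (a_free + Kd_pair)
    return pd.DataFrame(
        {
            "acceptor_uM": grid,
            "complex_uM": complexes,
            "intensity": baseline + signal_per_complex * complexes,
        }
    )
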