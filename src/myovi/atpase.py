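"""Steady-state actin-activated ATPase analysis (NADH-coupled assay).

ADP release is coupled to NADH oxidation, so the ATP turnover rate is the
slope of the OD340 time course divided by the NADH extinction coefficient
and the myosin concentration.  Rates versus actin concentration follow a
Michaelis-Menten law with a basal (actin-independent) term:

    Rate = V0 + kcat [Actin] / (K_actin + [Actin])

Dimerization is read out through *molecular gating*: in a dimer the two
heads coordinate so that only one turns over ATP at a time, roughly
halving the apparent kcat relative to the monomer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "ATPaseSeries",
    "MMParams",
    "GatingResult",
    "od_to_rate",
    "michaelis_basal",
    "fit_michaelis_basal",
    "gating_ratio",
]

#: NADH molar extinction coefficient at 340 nm (M^-1 cm^-1); standard
#: coupled-assay constant, overridable per call.
EPSILON_NADH = 6220.0

#: kcat(dimer)/kcat(monomer) at or below this is consistent with gating.
GATING_THRESHOLD = 0.7


@dataclass
class ATPaseSeries:
    actin_conc: np.ndarray  # µM
    rate: np.ndarray  # s^-1 per myosin head
    myosin_conc: float = float("nan")
    replicate: int = 0

    def __post_init__(self) -> None:
        self.actin_conc = np.asarray(self.actin_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(self.actin_conc < 0):
            raise ValueError("actin concentrations must be nonnegative")
        if np.any(self.rate < 0):
            raise ValueError("rates must be nonnegative")


@dataclass
class MMParams:
    V0: float
    kcat: float
    K_actin: float
    V0_err: float = float("nan")
    kcat_err: float = float("nan")
    K_actin_err: float = float("nan")
    flag: str = ""

    @property
    def valid(self) -> bool:
        return not self.flag


@dataclass
class GatingResult:
    ratio: float
    gating_consistent: bool


def od_to_rate(
    time_s: Sequence[float],
    od340: Sequence[float],
    myosin_conc: float,
    path_length: float = 1.0,
    epsilon: float = EPSILON_NADH,
    min_window_s: float = 60.0,
    r2_min: float = 0.99,
) -> float:
    """ATP turnover rate (s^-1 per head) from an OD340 time course.

    The steepest-sense conversion is |slope| / (epsilon * path) in M/s of
    NADH oxidized, divided by the myosin concentration.  The slope is
    taken over the longest window with linear-regression R^2 >=
    ``r2_min`` and duration >= ``min_window_s``; a perfectly flat course
    returns 0.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(od340, dtype=float)
    if myosin_conc <= 0:
        raise ValueError("myosin_conc must be > 0")
    if t[-1] - t[0] < min_window_s:
        raise ValueError("time course shorter than the minimum linear window")
    if np.ptp(y) == 0:
        return 0.0

    dt = np.median(np.diff(t))
    min_pts = max(int(round(min_window_s / dt)), 3)
    n = len(t)
    best = None
    # longest window first; slide within each length until one passes R^2
    for length in range(n, min_pts - 1, -1):
        for start in range(0, n - length + 1):
            tw = t[start : start + length]
            yw = y[start : start + length]
            slope, inter = np.polyfit(tw, yw, 1)
            pred = slope * tw + inter
            ss_res = np.sum((yw - pred) ** 2)
            ss_tot = np.sum((yw - yw.mean()) ** 2)
            if ss_tot == 0 or 1 - ss_res / ss_tot >= r2_min:
                best = slope
                break
        if best is not None:
            break
    if best is None:
        raise RuntimeError("no linear window with the required R^2 found")
    # OD/s -> M/s -> µM/s, then per µM myosin -> s^-1
    rate_uM_per_s = abs(best) / (epsilon * path_length) * 1e6
    return rate_uM_per_s / myosin_conc


def michaelis_basal(actin, V0, kcat, K_actin):
    """Eq: Rate = V0 + kcat*[Actin]/(K_actin + [Actin]); vectorized."""
    a = np.asarray(actin, dtype=float)
    return V0 + kcat * a / (K_actin + a)


def fit_michaelis_basal(series: ATPaseSeries, min_points: int = 5) -> MMParams:
    """Fit the basal + Michaelis-Menten law to an actin-activation series.

    The zero-actin point anchors the basal rate V0.  The fit is flagged
    when the actin grid does not reach K_actin/2 (half-saturation not
    identifiable from the data).
    """
    a, r = series.actin_conc, series.rate
    if len(np.unique(a)) < min_points:
        raise ValueError(f"need >= {min_points} distinct actin concentrations")
    if 0.0 not in a:
        raise ValueError("series must include a zero-actin (basal) point")

    v0_guess = float(r[a == 0].mean())
    kcat_guess = max(float(r.max()) - v0_guess, 1e-6)
    m = Model(michaelis_basal)
    params = m.make_params(
        V0=dict(value=v0_guess, min=0),
        kcat=dict(value=kcat_guess, min=0),
        K_actin=dict(value=max(np.median(a[a > 0]), 0.1), min=1e-6),
    )
    res = m.fit(r, params, actin=a)
    out = MMParams(
        V0=float(res.params["V0"].value),
        kcat=float(res.params["kcat"].value),
        K_actin=float(res.params["K_actin"].value),
        V0_err=float(res.params["V0"].stderr or np.nan),
        kcat_err=float(res.params["kcat"].stderr or np.nan),
        K_actin_err=float(res.params["K_actin"].stderr or np.nan),
    )
    if not res.success:
        out.flag = "optimizer did not converge"
    elif a.max() < out.K_actin / 2:
        out.flag = "K_actin unidentifiable: actin grid below K_actin/2"
    return out


def gating_ratio(monomer: MMParams, dimer: MMParams) -> GatingResult:
    """kcat(dimer)/kcat(monomer); <= 0.7 is annotated gating-consistent."""
    if monomer.kcat == 0:
        raise ValueError("monomer kcat is zero; ratio undefined")
    ratio = dimer.kcat / monomer.kcat
    return GatingResult(ratio=float(ratio), gating_consistent=bool(ratio <= GATING_THRESHOLD))
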