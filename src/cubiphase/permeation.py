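"""Franz-diffusion-cell permeation metrics.

A Franz cell measures drug transport across excised skin into a stirred
receptor compartment of volume ``V``; at each sampling time an aliquot
``V0`` is withdrawn and replaced with blank medium.  The cumulative
permeated amount per unit membrane area up to sample ``n`` is

    Q_n = [C_n · V + V0 · Σ_{i<n} C_i] / A        (µg/cm²)

which corrects the measured concentration ``C_n`` for the drug removed in
earlier aliquots.  The linear portion of Q(t) yields the steady-state flux
``J_ss`` (slope, µg·cm⁻²·h⁻¹) and lag time ``T_lag`` (t-intercept, h); the
enhancement ratio is the 5-h cumulative amount of the test formulation over
that of the reference solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PermeationSeries",
    "PermeationMetrics",
    "cumulative_amount",
    "flux_and_lag",
    "enhancement_ratio",
    "analyze_series",
    "read_permeation_series",
]

#: Franz-cell constants of the reference experiment: receptor volume (ml),
#: withdrawn aliquot (ml), effective diffusion area (cm²), schedule (h).
DEFAULT_V = 10.0
DEFAULT_V0 = 1.0
DEFAULT_AREA = 0.785
DEFAULT_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class PermeationSeries:
    """Receptor-compartment concentration–time series of one cell."""

    times: np.ndarray                  # h, ascending
    concentrations: np.ndarray         # µg/ml at each sampling
    V: float = DEFAULT_V
    V0: float = DEFAULT_V0
    A: float = DEFAULT_AREA
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.concentrations = np.asarray(self.concentrations, dtype=np.float64)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must align")
        if np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be positive and strictly ascending")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not (self.V >= self.V0 > 0):
            raise ValueError("need V >= V0 > 0")
        if not self.A > 0:
            raise ValueError("diffusion area must be positive")


@dataclass
class PermeationMetrics:
    Qn: np.ndarray                     # µg/cm² at each sampling time
    Jss: float                         # µg cm^-2 h^-1
    Tlag: float                        # h
    fit_window: Tuple[int, int]        # index range used (start, stop)
    ER: float | None = None
    flags: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Jss < 0:
            raise ValueError("Jss must be non-negative")


def cumulative_amount(s: PermeationSeries) -> np.ndarray:
    """Aliquot-corrected cumulative permeated amount per area, µg/cm²."""
    c = s.concentrations
    csum_prev = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return (c * s.V + s.V0 * csum_prev) / s.A


def flux_and_lag(times: Sequence[float], Qn: Sequence[float],
                 t_min: float = 1.0) -> Tuple[float, float, Tuple[int, int], Dict[str, object]]:
    """Steady-state flux and lag time from the linear portion of Q(t).

    The linear portion defaults to samples with t >= ``t_min`` (drops the
    first point of the standard 0.5–5 h schedule).  A negative t-intercept
    is clamped to 0 and flagged.

    Returns ``(Jss, Tlag, (start, stop), flags)``.
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(Qn, dtype=float)
    idx = np.flatnonzero(t >= t_min)
    if len(idx) < 2:
        raise ValueError("fit window must contain at least 2 points")
    tw, qw = t[idx], q[idx]
    if np.ptp(tw) == 0:
        raise ValueError("degenerate fit window: all times equal")
    slope, intercept = np.polyfit(tw, qw, 1)
    flags: Dict[str, object] = {}
    if slope <= 0:
        flags["nonpositive_slope"] = float(slope)
        return 0.0, 0.0, (int(idx[0]), int(idx[-1]) + 1), flags
    tlag = -intercept / slope
    if tlag < 0:
        flags["negative_lag_clamped"] = float(tlag)
        tlag = 0.0
    return float(slope), float(tlag), (int(idx[0]), int(idx[-1]) + 1), flags


def enhancement_ratio(Q_test: float, Q_reference: float) -> float:
    """Ratio of the test formulation's cumulative amount (at 5 h) to the
    reference solution's."""
    if Q_reference <= 0:
        raise ValueError("reference cumulative amount must be positive")
    return Q_test / Q_reference


def analyze_series(s: PermeationSeries, reference: PermeationSeries | None = None,
                   t_min: float = 1.0) -> PermeationMetrics:
    """Full per-cell analysis: Q_n profile, flux/lag fit, optional ER versus
    a reference series (compared at the final common sampling time)."""
    qn = cumulative_amount(s)
    jss, tlag, window, flags = flux_and_lag(s.times, qn, t_min=t_min)
    er = None
    if reference is not None:
        qr = cumulative_amount(reference)
        if not np.isclose(s.times[-1], reference.times[-1]):
            raise ValueError("ER requires matching final sampling times")
        er = enhancement_ratio(float(qn[-1]), float(qr[-1]))
    return PermeationMetrics(Qn=qn, Jss=jss, Tlag=tlag, fit_window=window,
                             ER=er, flags=flags)


def read_permeation_series(path, V: float = DEFAULT_V, V0: float = DEFAULT_V0,
                           A: float = DEFAULT_AREA, label: str = "") -> PermeationSeries:
    """Read a delimited series (columns ``time_h, conc_ug_ml``)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"time_h", "conc_ug_ml"} <= set(df.columns):
        raise ValueError("series file needs columns time_h, conc_ug_ml")
    return PermeationSeries(times=df["time_h"].to_numpy(dtype=float),
                            concentrations=df["conc_ug_ml"].to_numpy(dtype=float),
                            V=V, V0=V0, A=A, label=label or str(path))
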