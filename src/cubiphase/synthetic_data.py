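"""Synthetic inputs with known ground truth for every pipeline stage.

Laboratory inputs to the analysis stages (SAXS peak lists, Franz-cell
concentration series, xenograft measurements) and reference inputs to the
simulation stages (density fields, compositions, small bead systems) are
generated here with recorded truth, so each analyzer can be exercised as a
generator→analyzer round trip.  All generators are deterministic under a
fixed seed, and each returns ``(object, truth)`` where ``truth`` holds the
generating parameters.

Noise models: multiplicative Gaussian for peak positions and
concentrations, lognormal (mean-one) for tumor volumes and weights —
positivity-preserving, conventional for these measurement types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .dpd_engine import BeadSystem, DPDParams, Formulation, box_for_counts, init_system
from .permeation import (DEFAULT_AREA, DEFAULT_TIMES, DEFAULT_V, DEFAULT_V0,
                         PermeationSeries)
from .saxs_id import SPACE_GROUP_SEQUENCES, PeakList
from .struct_analysis import DensityField

__all__ = [
    "GeneratorSpec",
    "generate",
    "gen_saxs_peaks",
    "gen_permeation_series",
    "gen_tumor_study",
    "gen_density_field",
    "gen_dpd_fixture",
    "default_formulation_table",
    "STUDY_GROUPS",
]

#: Treatment arms of the reference xenograft study design: untreated control,
#: drug solution, blank cubic phase, drug-loaded cubic phase.
STUDY_GROUPS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    kind: str                       # saxs_peaks | permeation_series | tumor_study
    #                               # | density_field | formulation_table | dpd_fixture
    params: Mapping[str, object]
    seed: int = 0

    _KINDS = ("saxs_peaks", "permeation_series", "tumor_study",
              "density_field", "formulation_table", "dpd_fixture")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec to its generator; returns (object, truth)."""
    fn = {
        "saxs_peaks": gen_saxs_peaks,
        "permeation_series": gen_permeation_series,
        "tumor_study": gen_tumor_study,
        "density_field": gen_density_field,
        "dpd_fixture": gen_dpd_fixture,
    }
    if spec.kind == "formulation_table":
        table = default_formulation_table()
        return table, {"kind": spec.kind, "n": len(table)}
    out, truth = fn[spec.kind](**dict(spec.params), seed=spec.seed)
    truth["kind"] = spec.kind
    truth["seed"] = spec.seed
    return out, truth


# ---------------------------------------------------------------------------
# SAXS peaks
# ---------------------------------------------------------------------------

def gen_saxs_peaks(group: str, lattice_constant: float, n_peaks: int = 4,
                   noise_rel: float = 0.0, seed: int = 0,
                   offset: int = 0, sample: str = "") -> Tuple[PeakList, Dict]:
    """Bragg peaks q = 2π√N/a for the group's allowed reflections.

    ``offset`` starts the reflection window further into the allowed
    sequence (offset 3 for Pn3m yields the √6:√8 two-peak pattern commonly
    resolved for GMO cubic phases); each q is perturbed multiplicatively by
    Normal(0, noise_rel).
    """
    if group not in SPACE_GROUP_SEQUENCES:
        raise ValueError(f"unsupported space group {group!r}")
    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    seq = SPACE_GROUP_SEQUENCES[group][offset:offset + n_peaks]
    if len(seq) < n_peaks:
        raise ValueError("n_peaks exceeds the stored reflection sequence")
    q = 2.0 * np.pi * np.sqrt(seq) / lattice_constant
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        q = q * (1.0 + rng.normal(0.0, noise_rel, size=q.shape))
        q = np.sort(q)
    truth = {"group": group, "lattice_constant": float(lattice_constant),
             "reflections": [int(n) for n in seq], "offset": int(offset),
             "noise_rel": float(noise_rel)}
    return PeakList(q=q, sample=sample or f"{group}-{lattice_constant:g}"), truth


# ---------------------------------------------------------------------------
# Franz-cell series
# ---------------------------------------------------------------------------

def gen_permeation_series(Jss: float, Tlag: float = 0.0,
                          times: Sequence[float] = DEFAULT_TIMES,
                          V: float = DEFAULT_V, V0: float = DEFAULT_V0,
                          A: float = DEFAULT_AREA,
                          noise_rel: float = 0.0, seed: int = 0,
                          label: str = "") -> Tuple[PermeationSeries, Dict]:
    """Concentration series whose aliquot-corrected cumulative profile is
    Q(t) = max(0, Jss·(t − Tlag)).

    The target profile is inverted exactly through the cumulative-amount
    bookkeeping (C_n = (A·Q_n − V0·ΣC_i)/V in time order), then perturbed
    multiplicatively by Normal(0, noise_rel).
    """
    if Jss < 0:
        raise ValueError("Jss must be non-negative")
    t = np.asarray(times, dtype=float)
    q_target = np.maximum(0.0, Jss * (t - Tlag))
    conc = np.empty_like(q_target)
    csum = 0.0
    for n in range(len(t)):
        c = (A * q_target[n] - V0 * csum) / V
        if c < -1e-9:
            raise ValueError(
                f"inconsistent Tlag/schedule: exact inversion gives negative "
                f"concentration at t={t[n]} h")
        conc[n] = max(0.0, c)
        csum += conc[n]
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        conc = np.maximum(0.0, conc * (1.0 + rng.normal(0.0, noise_rel, size=conc.shape)))
    truth = {"Jss": float(Jss), "Tlag": float(Tlag), "noise_rel": float(noise_rel),
             "V": V, "V0": V0, "A": A}
    return PermeationSeries(times=t, concentrations=conc, V=V, V0=V0, A=A,
                            label=label), truth


# ---------------------------------------------------------------------------
# xenograft study
# ---------------------------------------------------------------------------

def gen_tumor_study(n_per_group: int = 6,
                    growth_rate: float = 0.25,
                    inhibition_by_group: Mapping[str, float] | None = None,
                    days: int = 10,
                    noise_cv: float = 0.0,
                    seed: int = 0,
                    v0_mm3: float = 75.0,
                    control_mean_weight_g: float = 1.73,
                    aspect_ratio: float = 1.2) -> Tuple[Dict[str, object], Dict]:
    """Synthetic xenograft study: daily caliper measurements and terminal weights.

    Per-mouse volumes grow exponentially, V(t) = V0·exp(r·(1−i_g)·t), with
    mean-one lognormal measurement noise of coefficient of variation
    ``noise_cv``; L and W are back-solved from V at a fixed aspect ratio
    L = aspect_ratio · W.  Terminal weights are drawn with group means
    control_mean × (1 − i_g), so at zero noise the inhibition-rate analysis
    recovers each group's inhibition exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    inh = dict(inhibition_by_group
               if inhibition_by_group is not None
               else {"I": 0.0, "II": 0.11, "III": 0.06, "IV": 0.64})
    for g, i in inh.items():
        if not 0.0 <= i < 1.0:
            raise ValueError(f"inhibition of group {g} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(noise_cv**2)
    mu = -0.5 * sigma2
    sd = np.sqrt(sigma2)

    def noise(size=None):
        return np.exp(rng.normal(mu, sd, size=size)) if noise_cv > 0 else (
            np.ones(size) if size else 1.0)

    rows = []
    weights: Dict[str, np.ndarray] = {}
    for g in inh:
        w_group = []
        for m in range(n_per_group):
            mouse = f"{g}-{m + 1}"
            for day in range(days + 1):
                v = v0_mm3 * np.exp(growth_rate * (1.0 - inh[g]) * day) * noise()
                w_diam = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
                rows.append({"mouse_id": mouse, "group": g, "day": day,
                             "l_mm": aspect_ratio * w_diam, "w_mm": w_diam,
                             "volume_mm3": v})
            w_group.append(control_mean_weight_g * (1.0 - inh[g]) * noise())
        weights[g] = np.asarray(w_group, dtype=float)
    measurements = pd.DataFrame(rows)
    truth = {"inhibition_by_group": inh, "growth_rate": growth_rate,
             "days": days, "noise_cv": noise_cv, "n_per_group": n_per_group,
             "control_mean_weight_g": control_mean_weight_g}
    return {"measurements": measurements, "weights": weights}, truth


# ---------------------------------------------------------------------------
# density fields
# ---------------------------------------------------------------------------

def gen_density_field(phase: str, grid_n: int = 32,
                      box: Sequence[float] = (8.0, 8.0, 8.0),
                      noise: float = 0.0, seed: int = 0,
                      n_periods: int = 1,
                      lamellar_k: int = 2) -> Tuple[DensityField, Dict]:
    """Reference density field of a known phase for classifier testing.

    ``bicontinuous_cubic`` is the positive-shifted Schwarz-D nodal field
    cos x cos y cos z − sin x sin y sin z (``n_periods`` per box edge) whose
    two level sets both percolate triply; ``lamellar`` is
    1 + cos(2π·k·z/L_z); ``disordered`` is a constant.  Additive Gaussian
    noise of amplitude ``noise`` is applied, clipped at zero to keep the
    field a density.
    """
    if phase not in ("bicontinuous_cubic", "lamellar", "disordered"):
        raise ValueError(f"unsupported phase {phase!r}")
    box = np.asarray(box, dtype=float)
    coords = [2.0 * np.pi * (np.arange(grid_n) + 0.5) / grid_n for _ in range(3)]
    if phase == "bicontinuous_cubic":
        x, y, z = np.meshgrid(*(c * n_periods for c in coords), indexing="ij")
        f = np.cos(x) * np.cos(y) * np.cos(z) - np.sin(x) * np.sin(y) * np.sin(z)
        grid = f + 2.0      # positive shift; threshold-at-mean is unaffected
    elif phase == "lamellar":
        z = coords[2] * lamellar_k
        grid = 1.0 + np.cos(z)[None, None, :] * np.ones((grid_n, grid_n, 1))
    else:
        grid = np.full((grid_n, grid_n, grid_n), 1.0)
    if noise > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise, size=grid.shape)
    grid = np.maximum(grid, 0.0)
    truth = {"phase": phase, "grid_n": grid_n, "noise": float(noise),
             "n_periods": n_periods, "lamellar_k": lamellar_k}
    return DensityField(grid=grid, box=box, n_frames_averaged=1), truth


# ---------------------------------------------------------------------------
# small bead systems
# ---------------------------------------------------------------------------

def gen_dpd_fixture(counts: Mapping[str, int] | None = None,
                    params: DPDParams | None = None,
                    seed: int = 0) -> Tuple[BeadSystem, Dict]:
    """A small seeded BeadSystem (default: 60 water + 20 A–B dimers) for
    force-oracle and I/O tests."""
    counts = dict(counts) if counts is not None else {"A": 20, "B": 20, "WATER": 60}
    params = params or DPDParams()
    box = box_for_counts(counts, rho=params.rho)
    system = init_system(counts, box, params, seed=seed)
    return system, {"counts": counts, "box": box.tolist()}


# ---------------------------------------------------------------------------
# reference composition table
# ---------------------------------------------------------------------------

def default_formulation_table() -> list[Formulation]:
    """The six reference GMO/ethanol/water/Met compositions F1–F6
    (mass parts 64/x/30/5 with x = 0, 2, 4, 6, 8, 10)."""
    ethanol = {"F1": 0, "F2": 2, "F3": 4, "F4": 6, "F5": 8, "F6": 10}
    return [Formulation(name, {"GMO": 64.0, "ETHANOL": float(e),
                               "WATER": 30.0, "MET": 5.0})
            for name, e in ethanol.items()]
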