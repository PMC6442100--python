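"""SAXS peak indexing for lyotropic liquid-crystal mesophases.

Bragg peak positions of a mesophase follow ``q = 2π√N / a`` where the
allowed ``N = h² + k² + l²`` sequence is characteristic of the space group
(Pn3m: 2,3,4,6,8,9…; Im3m: 2,4,6,8…; Ia3d: 6,8,14,16…) — for a lamellar
stack ``q = 2πn/d`` and for a 2-D hexagonal phase ``N ∈ 1,3,4,7…``.  An
observed peak list is indexed by sliding it along each candidate group's
allowed sequence (so a two-peak pattern may match e.g. the √6:√8 positions),
fitting the lattice constant by zero-intercept least squares and keeping
the assignment with minimal RMS relative residual.

GMO/water cubic phases index as Pn3m in this system; the candidate priority
order reflects that when a short peak list fits several groups exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "PhaseAssignment",
    "SPACE_GROUP_SEQUENCES",
    "DEFAULT_CANDIDATES",
    "index_peaks",
    "lattice_from_fit",
    "spacing_ratio_string",
    "read_peak_lists",
]

#: Allowed N = h²+k²+l² sequences per supported symmetry (lamellar uses n²
#: so that q ratios are 1:2:3…; hexagonal uses the 2-D h²+hk+k² sequence).
SPACE_GROUP_SEQUENCES: Dict[str, Tuple[int, ...]] = {
    "Pn3m": (2, 3, 4, 6, 8, 9, 10, 11, 12, 14),
    "Im3m": (2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    "Ia3d": (6, 8, 14, 16, 20, 22, 24, 26, 30, 32),
    "hexagonal": (1, 3, 4, 7, 9, 12, 13, 16),
    "lamellar": (1, 4, 9, 16, 25, 36),
}

#: Priority order used to break exact-fit ties on short peak lists.
DEFAULT_CANDIDATES: Tuple[str, ...] = ("Pn3m", "Im3m", "Ia3d", "hexagonal", "lamellar")

#: Miller indices reported for the leading allowed reflections.
_MILLER: Dict[str, Dict[int, Tuple[int, int, int]]] = {
    "Pn3m": {2: (1, 1, 0), 3: (1, 1, 1), 4: (2, 0, 0), 6: (2, 1, 1), 8: (2, 2, 0),
             9: (2, 2, 1), 10: (3, 1, 0), 11: (3, 1, 1), 12: (2, 2, 2), 14: (3, 2, 1)},
    "Im3m": {2: (1, 1, 0), 4: (2, 0, 0), 6: (2, 1, 1), 8: (2, 2, 0), 10: (3, 1, 0),
             12: (2, 2, 2), 14: (3, 2, 1), 16: (4, 0, 0), 18: (4, 1, 1), 20: (4, 2, 0)},
    "Ia3d": {6: (2, 1, 1), 8: (2, 2, 0), 14: (3, 2, 1), 16: (4, 0, 0), 20: (4, 2, 0),
             22: (3, 3, 2), 24: (4, 2, 2), 26: (4, 3, 1), 30: (5, 2, 1), 32: (4, 4, 0)},
}


@dataclass
class PeakList:
    """Ascending scattering-vector magnitudes (Å⁻¹) of one sample."""

    q: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        if self.q.ndim != 1 or len(self.q) < 1:
            raise ValueError("q must be a 1-D list of peaks")
        if np.any(self.q <= 0):
            raise ValueError("q values must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q values must be strictly increasing")


@dataclass
class PhaseAssignment:
    """Indexing result: symmetry, lattice constant and per-peak assignment."""

    space_group: str
    lattice_constant: float            # Å (lamellar: repeat distance d)
    residual: float                    # RMS relative q error
    miller_indices: List[Tuple[int, int, int]]
    spacing_ratio: str
    offset: int = 0
    lattice_constant_se: float = 0.0
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lattice_constant <= 0:
            raise ValueError("lattice constant must be positive")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def spacing_ratio_string(q: Sequence[float], decimals: int = 2) -> str:
    """Observed q ratios relative to the first peak, e.g. ``'1:1.15'``.

    Ratio-only reporting mode for patterns whose printed ratios do not admit
    a physical indexing (used for the lamellar samples reported with 4:5 and
    3:4 ratios).
    """
    q = np.asarray(q, dtype=float)
    r = q / q[0]
    return ":".join(f"{x:.{decimals}g}" for x in r)


def lattice_from_fit(q: Sequence[float], sqrt_n: Sequence[float]) -> Tuple[float, float]:
    """Lattice constant (and standard error) from the zero-intercept line
    q = (2π/a)·√N."""
    q = np.asarray(q, dtype=float)
    s = np.asarray(sqrt_n, dtype=float)
    if len(q) != len(s) or len(q) < 2:
        raise ValueError("need equal-length q and sqrt(N) lists with >= 2 entries")
    if len(np.unique(q)) != len(q):
        raise ValueError("duplicate q values cannot index distinct reflections")
    slope = float(np.dot(q, s) / np.dot(s, s))
    if slope <= 0:
        raise ValueError("non-physical (non-positive) fitted slope")
    resid = q - slope * s
    dof = max(1, len(q) - 1)
    slope_var = float(np.dot(resid, resid) / dof / np.dot(s, s))
    a = 2.0 * np.pi / slope
    # delta-method propagation: a = 2π/slope
    a_se = a * np.sqrt(slope_var) / slope
    return a, a_se


#: Conventional assignment of short (two-peak) cubic patterns: GMO-based
#: Pn3m phases are indexed on the strong 211/220 reflections (N = 6, 8).
PREFERRED_WINDOWS: Dict[str, Tuple[int, ...]] = {"Pn3m": (6, 8)}


def index_peaks(peaks: PeakList,
                candidates: Sequence[str] = DEFAULT_CANDIDATES,
                max_offset: int = 3,
                residual_cap: float = 0.02,
                preferred_windows: Dict[str, Tuple[int, ...]] | None = None
                ) -> PhaseAssignment:
    """Index a peak list against candidate symmetries.

    For each candidate the observed peaks are matched, in order, to a
    contiguous window of the group's allowed √N sequence starting at offset
    0..``max_offset``; the lattice constant is fitted by zero-intercept
    least squares on q = 2π√N/a.  The assignment with minimal RMS relative
    residual wins; exact ties go to the earlier candidate in ``candidates``,
    then to a conventionally preferred reflection window (two-peak cubic
    patterns with the ratio √8/√6 = √4/√3 are genuinely ambiguous within
    Pn3m and are assigned to the strong 211/220 reflections by convention),
    then to the smaller offset.  Raises if every residual exceeds
    ``residual_cap``.
    """
    if len(peaks.q) < 2:
        raise ValueError("need at least 2 peaks for an assignment")
    preferred = PREFERRED_WINDOWS if preferred_windows is None else preferred_windows
    best = None
    for prio, group in enumerate(candidates):
        if group not in SPACE_GROUP_SEQUENCES:
            raise ValueError(f"unsupported space group {group!r}")
        seq = SPACE_GROUP_SEQUENCES[group]
        for offset in range(0, max_offset + 1):
            window = seq[offset:offset + len(peaks.q)]
            if len(window) < len(peaks.q):
                break
            sqrt_n = np.sqrt(window)
            try:
                a, a_se = lattice_from_fit(peaks.q, sqrt_n)
            except ValueError:
                continue
            pred = 2.0 * np.pi * sqrt_n / a
            residual = float(np.sqrt(np.mean(((pred - peaks.q) / peaks.q) ** 2)))
            not_preferred = int(tuple(window) != preferred.get(group, ()))
            # residual quantized so that numerically-identical fits tie
            key = (round(residual * 1e9), prio, not_preferred, offset)
            if best is None or key < best[0]:
                best = (key, group, offset, a, a_se, window, residual)
    if best is None:
        raise ValueError("no candidate assignment possible")
    _, group, offset, a, a_se, window, residual = best
    if residual > residual_cap:
        raise ValueError(
            f"unassigned: best candidate {group} (offset {offset}) has RMS "
            f"relative residual {residual:.4f} > cap {residual_cap}")
    if group == "lamellar":
        miller = [(n, 0, 0) for n in range(offset + 1, offset + 1 + len(peaks.q))]
        ratio = ":".join(str(n) for n, _, _ in miller)
    elif group == "hexagonal":
        miller = [(0, 0, 0)] * len(peaks.q)  # 2-D (h,k) indexing not expanded
        ratio = ":".join(f"√{n}" for n in window)
    else:
        miller = [_MILLER[group][n] for n in window]
        ratio = ":".join(f"√{n}" for n in window)
    return PhaseAssignment(space_group=group, lattice_constant=a, residual=residual,
                           miller_indices=miller, spacing_ratio=ratio, offset=offset,
                           lattice_constant_se=a_se,
                           diagnostics={"sample": peaks.sample,
                                        "n_peaks": len(peaks.q),
                                        "candidates": list(candidates)})


def read_peak_lists(path) -> List[PeakList]:
    """Read delimited peak lists (columns ``sample, q``), one PeakList per sample."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"sample", "q"} <= set(df.columns):
        raise ValueError("peak file needs columns sample, q")
    out = []
    for sample, grp in df.groupby("sample", sort=False):
        out.append(PeakList(q=np.sort(grp["q"].to_numpy(dtype=float)), sample=str(sample)))
    return out
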