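"""Xenograft efficacy metrics and group comparisons.

Tumor volume from caliper measurements follows the standard ellipsoid
approximation ``V = 0.5 · L · W²`` (L the largest, W the smallest
superficial diameter); the tumor inhibitory rate of a therapy group is
``(W_blank − W_test) / W_blank × 100%`` on mean terminal tumor weights.
Group comparisons use a two-sample t-test (2 groups) or one-way ANOVA
followed, when the omnibus test rejects, by the Student–Newman–Keuls (SNK)
stepwise multiple-range procedure on the studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TumorMeasurement",
    "GroupSummary",
    "tumor_volume",
    "inhibition_rate",
    "compare_groups",
    "summarize_groups",
    "read_measurements",
    "read_weights",
]


def _round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement of one mouse on one day (diameters in mm)."""

    mouse_id: str
    day: int
    L: float
    W: float

    def __post_init__(self) -> None:
        if not (self.L >= self.W > 0):
            raise ValueError(f"need L >= W > 0, got L={self.L}, W={self.W}")

    @property
    def volume(self) -> float:
        return tumor_volume(self.L, self.W)


@dataclass
class GroupSummary:
    """Terminal-weight summary of one treatment group."""

    group: str
    terminal_weights: np.ndarray       # g per mouse
    mean_weight: float
    sd_weight: float
    inhibition_rate: float | None = None   # %, absent for the control group

    def __post_init__(self) -> None:
        self.terminal_weights = np.asarray(self.terminal_weights, dtype=float)
        if np.any(self.terminal_weights <= 0):
            raise ValueError("terminal weights must be positive")


def tumor_volume(L: float, W: float) -> float:
    """Ellipsoid caliper volume 0.5·L·W² (mm³)."""
    if W > L:
        raise ValueError("measurement convention violated: W must not exceed L")
    if not W > 0:
        raise ValueError("diameters must be positive")
    return 0.5 * L * W * W


def inhibition_rate(W_blank: float, W_test: float, decimals: int = 2) -> float:
    """Tumor inhibitory rate (W_blank − W_test)/W_blank × 100%, reported
    rounded half-up to ``decimals``."""
    if W_blank <= 0:
        raise ValueError("control mean weight must be positive")
    rate = (W_blank - W_test) / W_blank * 100.0
    return _round_half_up(rate, decimals)


def summarize_groups(weights: Mapping[str, Sequence[float]],
                     control: str) -> List[GroupSummary]:
    """Per-group terminal-weight summaries with inhibition rates versus the
    designated control group."""
    if control not in weights:
        raise ValueError(f"control group {control!r} not in weights")
    blank_mean = float(np.mean(weights[control]))
    out = []
    for group, w in weights.items():
        w = np.asarray(w, dtype=float)
        rate = None if group == control else inhibition_rate(blank_mean, float(w.mean()))
        out.append(GroupSummary(group=group, terminal_weights=w,
                                mean_weight=float(w.mean()),
                                sd_weight=float(w.std(ddof=1)) if len(w) > 1 else 0.0,
                                inhibition_rate=rate))
    return out


# ---------------------------------------------------------------------------
# group comparison: t-test / ANOVA + SNK
# ---------------------------------------------------------------------------

def _snk(groups: Mapping[str, np.ndarray], alpha: float) -> List[Dict[str, object]]:
    """Student–Newman–Keuls stepwise multiple-range test.

    Group means are ranked; the range spanning p ordered means is tested
    against the studentized-range quantile q(alpha, p, df) with the pooled
    within-group mean square.  A non-significant range protects all ranges
    nested inside it (the stepwise rule).  Unequal n use the harmonic mean.
    """
    names = list(groups)
    means = {g: float(np.mean(groups[g])) for g in names}
    ns = {g: len(groups[g]) for g in names}
    df_within = sum(ns[g] - 1 for g in names)
    mse = sum(float(np.sum((groups[g] - means[g]) ** 2)) for g in names) / df_within
    order = sorted(names, key=lambda g: means[g])
    k = len(order)
    nonsig_spans: List[Tuple[int, int]] = []
    results = []
    for span in range(k, 1, -1):
        for start in range(0, k - span + 1):
            i, j = start, start + span - 1
            g_lo, g_hi = order[i], order[j]
            protected = any(a <= i and j <= b for a, b in nonsig_spans)
            n_h = 2.0 / (1.0 / ns[g_lo] + 1.0 / ns[g_hi])
            se = np.sqrt(mse / n_h)
            q_obs = (means[g_hi] - means[g_lo]) / se if se > 0 else np.inf
            p_val = float(stats.studentized_range.sf(q_obs, span, df_within))
            significant = (not protected) and p_val < alpha
            if not significant:
                nonsig_spans.append((i, j))
            results.append({"pair": (g_lo, g_hi), "span": span, "q": float(q_obs),
                            "p": p_val if not protected else None,
                            "protected": protected, "significant": significant})
    return results


def compare_groups(groups: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> Dict[str, object]:
    """Two-sample t-test (2 groups) or one-way ANOVA + SNK (>2 groups).

    Returns a report dict with the omnibus statistic/p-value and, when the
    ANOVA rejects at ``alpha``, the SNK pairwise results.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    if all(np.allclose(v, v.mean()) for v in arrays.values()):
        raise ValueError("zero within-group variance everywhere; no valid comparison")
    report: Dict[str, object] = {"alpha": alpha, "groups": {g: len(v) for g, v in arrays.items()}}
    if len(arrays) == 2:
        (ga, va), (gb, vb) = arrays.items()
        t, p = stats.ttest_ind(va, vb)
        report.update(test="t-test", statistic=float(t), p_value=float(p),
                      significant=bool(p < alpha), pair=(ga, gb))
    else:
        f, p = stats.f_oneway(*arrays.values())
        report.update(test="anova", statistic=float(f), p_value=float(p),
                      significant=bool(p < alpha))
        if p < alpha:
            report["snk"] = _snk(arrays, alpha)
    return report


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_measurements(path) -> pd.DataFrame:
    """Caliper measurement table (mouse_id, group, day, L_mm, W_mm) with a
    derived volume_mm3 column."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = {"mouse_id", "group", "day", "l_mm", "w_mm"}
    if not needed <= set(df.columns):
        raise ValueError(f"measurement table needs columns {sorted(needed)}")
    df["volume_mm3"] = [tumor_volume(l, w) for l, w in zip(df["l_mm"], df["w_mm"])]
    return df


def read_weights(path) -> Dict[str, np.ndarray]:
    """Terminal-weight table (mouse_id, group, weight_g) → per-group arrays."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"group", "weight_g"} <= set(df.columns):
        raise ValueError("weight table needs columns group, weight_g")
    return {str(g): grp["weight_g"].to_numpy(dtype=float)
            for g, grp in df.groupby("group", sort=False)}
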