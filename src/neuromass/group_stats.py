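"""Group comparison and regression of fitted coupling vs graph metrics.

Two analyses relate the cohort's structure and model fits:

1. Wilcoxon rank-sum tests (control vs stroke) on each of the three
   graph metrics, against a Bonferroni-corrected threshold
   0.05 / 3 ≈ 0.017.
2. Simple linear regression of each graph metric (dependent) on the
   fitted long-range coupling G (independent), reporting slope,
   intercept, the slope t statistic and its two-sided p value with
   n − 2 degrees of freedom, and r².

The rank-sum test uses the exact null distribution when the smaller
sample has at most 10 observations and there are no ties, and the normal
approximation with tie correction (no continuity correction) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStatsResult",
    "wilcoxon_rank_sum",
    "bonferroni_threshold",
    "simple_linear_regression",
    "run_group_analysis",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("degree_centrality", "betweenness_centrality", "global_efficiency")

#: switch to the exact rank-sum null when min(n_a, n_b) is at most this
EXACT_SWITCH_N = 10


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns ``(W, p)`` where ``W`` is the rank-sum of the first sample
    (midranks for ties).  Exact when ``min(n_a, n_b) <= 10`` and the
    pooled sample is tie-free; otherwise the normal approximation with
    tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= EXACT_SWITCH_N and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)  # U -> rank-sum
    return w, float(min(res.pvalue, 1.0))


def bonferroni_threshold(family_alpha: float = 0.05, n_tests: int = 3
                         ) -> tuple[float, float]:
    """Per-test significance threshold ``family_alpha / n_tests``,
    returned raw and rounded to 3 decimals (0.05 / 3 → 0.017)."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    raw = family_alpha / n_tests
    return raw, round(raw, 3)


def simple_linear_regression(x, y) -> dict:
    """Ordinary least squares of ``y`` on ``x``.

    Returns slope, intercept, the slope t statistic (slope / SE), its
    two-sided p value (t distribution, n − 2 df) and r².  Requires
    n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    if not np.isfinite(res.stderr) or res.stderr == 0:  # exact fit / constant y
        t = 0.0 if res.slope == 0 else np.inf * np.sign(res.slope)
        p = 1.0 if res.slope == 0 else 0.0
    else:
        t = float(res.slope / res.stderr)
        p = float(2.0 * stats.t.sf(abs(t), x.size - 2))
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # constant y: no variance to explain
        r2 = 1.0 if res.slope != 0 else 0.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "t": float(t),
        "p": float(p),
        "r_squared": r2,
        "n": int(x.size),
    }


@dataclass
class GroupStatsResult:
    """Wilcoxon and regression outputs for the three graph metrics."""

    wilcoxon: dict  # metric -> {"statistic", "p"}
    regression: dict  # metric -> simple_linear_regression output
    bonferroni_alpha_raw: float
    bonferroni_alpha: float
    n_control: int
    n_stroke: int
    significant_metrics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "wilcoxon": self.wilcoxon,
            "regression": self.regression,
            "bonferroni_alpha_raw": self.bonferroni_alpha_raw,
            "bonferroni_alpha": self.bonferroni_alpha,
            "n_control": self.n_control,
            "n_stroke": self.n_stroke,
            "significant_metrics": list(self.significant_metrics),
        }


def run_group_analysis(table: pd.DataFrame, family_alpha: float = 0.05
                       ) -> GroupStatsResult:
    """Full two-part analysis on a cohort metrics table.

    The table needs columns ``group`` (control/stroke), ``G``, and the
    three metric columns; both groups must have at least 2 subjects.
    """
    missing = [c for c in ("group", "G", *METRIC_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    control = table[table["group"] == "control"]
    stroke = table[table["group"] == "stroke"]
    if len(control) < 2 or len(stroke) < 2:
        raise ValueError("need at least 2 subjects per group")
    raw, rounded = bonferroni_threshold(family_alpha, len(METRIC_COLUMNS))
    wilcoxon = {}
    significant = []
    for metric in METRIC_COLUMNS:
        w, p = wilcoxon_rank_sum(control[metric].to_numpy(),
                                 stroke[metric].to_numpy())
        wilcoxon[metric] = {"statistic": w, "p": p}
        if p < raw:
            significant.append(metric)
    regression = {}
    for metric in METRIC_COLUMNS:
        try:
            regression[metric] = simple_linear_regression(
                table["G"].to_numpy(), table[metric].to_numpy())
        except ValueError as exc:  # e.g. every subject fitted the same G
            regression[metric] = {"error": str(exc)}
    return GroupStatsResult(
        wilcoxon=wilcoxon,
        regression=regression,
        bonferroni_alpha_raw=raw,
        bonferroni_alpha=rounded,
        n_control=len(control),
        n_stroke=len(stroke),
        significant_metrics=significant,
    )
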