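"""Group-comparison statistics for derived behavioral metrics.

Criterion-attainment comparisons use survival-style tests on (ETC or HTC,
reached) pairs: the log-rank test and the Gehan-Breslow generalized Wilcoxon
test (risk-set-size weights, which emphasize early differences), both
delegated to lifelines. Censored animals (never reached criterion) stay in
the risk set until their censoring value, per the standard convention.

Scalar metrics (learning indices, flexibility) are compared by classical
one-way ANOVA with Tukey HSD or Sidak-adjusted pairwise follow-ups.

The mitochondrial respirometry coupling-efficiency formula, 1 - GM/S (one
minus the ratio of glutamate/malate-supported to succinate-state oxygen
consumption after non-mitochondrial baseline subtraction), lives here too: a
lower value means a smaller fraction of succinate-state respiration is
engaged under complex-I substrates alone.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "SurvivalComparison",
    "AnovaResult",
    "RespirometryStates",
    "logrank_test",
    "gehan_wilcoxon_test",
    "one_way_anova",
    "tukey_hsd",
    "sidak_adjust",
    "coupling_efficiency",
]


@dataclass(frozen=True)
class SurvivalComparison:
    test: str
    groups: tuple[str, ...]
    chi_square: float
    df: int
    p_value: float


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    zero_within_variance: bool = False
    pairwise: pd.DataFrame | None = field(default=None, repr=False)


def _prepare_survival(results: pd.DataFrame, axis: str):
    col = {"entries": "etc", "hours": "htc"}.get(axis)
    if col is None:
        raise ValueError("axis must be 'entries' or 'hours'")
    groups = results["group"].astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("every group needs at least one subject")
    return (
        results[col].to_numpy(dtype=float),
        results["reached"].to_numpy(dtype=bool).astype(int),
        groups.to_numpy(),
    )


def logrank_test(results: pd.DataFrame, axis: str = "entries") -> SurvivalComparison:
    """Multi-group log-rank test on a criterion-results frame.

    ``results`` needs columns ``group``, ``reached``, and the axis column
    (``etc`` or ``htc``); non-reachers are censored at their recorded value.
    """
    durations, observed, groups = _prepare_survival(results, axis)
    res = multivariate_logrank_test(durations, groups, observed)
    return SurvivalComparison(
        test="log-rank",
        groups=tuple(sorted(set(groups))),
        chi_square=float(res.test_statistic),
        df=len(set(groups)) - 1,
        p_value=float(res.p_value),
    )


def gehan_wilcoxon_test(results: pd.DataFrame, axis: str = "entries") -> SurvivalComparison:
    """Gehan-Breslow generalized Wilcoxon test (n-at-risk weighted log-rank)."""
    durations, observed, groups = _prepare_survival(results, axis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lifelines warns about the weighting name
        res = multivariate_logrank_test(durations, groups, observed, weightings="wilcoxon")
    return SurvivalComparison(
        test="gehan-wilcoxon",
        groups=tuple(sorted(set(groups))),
        chi_square=float(res.test_statistic),
        df=len(set(groups)) - 1,
        p_value=float(res.p_value),
    )


def one_way_anova(groups: dict) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on a mapping name -> values.

    Computed from the explicit between/within sum-of-squares decomposition so
    the degenerate zero-within-variance case can be reported as an infinite F
    with p -> 0 (flagged) instead of failing.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_vals) - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(math.inf, df_b, df_w, 0.0, zero_within_variance=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def tukey_hsd(groups: dict) -> pd.DataFrame:
    """All pairwise comparisons with Tukey HSD (studentized-range) adjusted p.

    Returns a tidy frame: group_a, group_b, mean_diff, p_adjusted.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adjusted": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


@dataclass(frozen=True)
class RespirometryStates:
    """Baseline-corrected oxygen-consumption states for coupling efficiency.

    ``ocr_gm``: rate with glutamate/malate (complex-I substrates);
    ``ocr_s``: rate in the succinate-supported state; ``baseline``: the
    antimycin-A (non-mitochondrial) rate subtracted from both. All in
    pmol O2 s^-1 mg^-1.
    """

    ocr_gm: float
    ocr_s: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.ocr_gm - self.baseline < 0:
            raise ValueError("GM rate below baseline: negative after correction")
        if self.ocr_s - self.baseline <= 0:
            raise ValueError("succinate-state rate must exceed baseline")


def coupling_efficiency(states: RespirometryStates) -> float:
    """OXPHOS coupling efficiency 1 - GM/S on baseline-corrected rates.

    GM > S yields a negative efficiency; it is returned as-is with a warning
    rather than silently clamped, since it indicates an inconsistent
    measurement.
    """
    gm = states.ocr_gm - states.baseline
    s = states.ocr_s - states.baseline
    eff = 1.0 - gm / s
    if eff < 0:
        warnings.warn(
            f"negative coupling efficiency ({eff:.3f}): GM state exceeds succinate state",
            stacklevel=2,
        )
    return eff
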