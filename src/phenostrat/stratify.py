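"""Young-reference cutoff, intact/impaired classification, z-scores, embedding.

Aged cohorts are stratified against a reference interval computed from young
animals' reversal entries-to-criterion (ETC): the upper bound of the 90%
confidence interval of the young mean (mean + t-quantile x SEM) is rounded up
to the nearest 100 entries to give an operational cutoff. Under the young
reference summary used here (mean 813.03, SEM 105.92, n = 40) the raw bound
is ~991.5 entries and the operational cutoff 1,000 entries. Aged animals with
reversal ETC strictly below the cutoff are classified cognitively *intact*;
animals at or above it, or that never reached criterion (censored), are
*impaired*.

A percentile-based reference interval (an empirical quantile of the young ETC
values) is available as an alternative cutoff method.

For joint molecular-behavioral visualization, a feature matrix is reduced to
its top two principal components and a behavioral z-score (typically of
cognitive flexibility) is appended as the third coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ReferenceCutoff",
    "Embedding3D",
    "compute_reference_cutoff",
    "classify_etc",
    "classify_cohort",
    "simulate_classification_fractions",
    "zscore_series",
    "augment_embedding",
]

INTACT = "intact"
IMPAIRED = "impaired"


@dataclass(frozen=True)
class ReferenceCutoff:
    """Operational stratification threshold derived from a young reference."""

    metric: str
    n_ref: int
    mean_ref: float
    sem_ref: float
    ci_level: float
    raw_upper_bound: float
    cutoff: float
    method: str = "t_ci"
    rounding: str = "ceil_to_100"


def _round_up(x: float, rule: str) -> float:
    if rule == "ceil_to_100":
        return 100.0 * math.ceil(x / 100.0 - 1e-12)
    if rule == "none":
        return x
    raise ValueError(f"unknown rounding rule {rule!r}")


def compute_reference_cutoff(
    values=None,
    *,
    mean: float | None = None,
    sem: float | None = None,
    n: int | None = None,
    ci_level: float = 0.90,
    rounding: str = "ceil_to_100",
    method: str = "t_ci",
    metric: str = "reversal_etc",
) -> ReferenceCutoff:
    """Compute the young-reference cutoff from raw values or a summary.

    ``method="t_ci"`` (default) takes the upper bound of the two-sided
    ``ci_level`` confidence interval of the mean, ``mean + t_{(1+ci)/2, n-1}
    * SEM``. ``method="percentile"`` takes the empirical ``(1+ci)/2``
    quantile of the raw values instead (raw values required). The bound is
    then rounded up per ``rounding`` to give the operational cutoff.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    if values is not None:
        vals = np.asarray(values, dtype=float)
        n = len(vals)
        if n < 2:
            raise ValueError("need at least two reference animals")
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / math.sqrt(n))
    else:
        if mean is None or sem is None or n is None:
            raise ValueError("provide raw values or all of mean/sem/n")
        if n < 2:
            raise ValueError("need at least two reference animals")
        if sem < 0:
            raise ValueError("sem must be non-negative")

    upper_q = (1.0 + ci_level) / 2.0
    if method == "t_ci":
        raw = mean + sps.t.ppf(upper_q, df=n - 1) * sem if sem > 0 else mean
    elif method == "percentile":
        if values is None:
            raise ValueError("percentile method requires raw reference values")
        raw = float(np.quantile(vals, upper_q))
    else:
        raise ValueError(f"unknown cutoff method {method!r}")

    return ReferenceCutoff(
        metric=metric,
        n_ref=int(n),
        mean_ref=float(mean),
        sem_ref=float(sem),
        ci_level=ci_level,
        raw_upper_bound=float(raw),
        cutoff=_round_up(float(raw), rounding),
        method=method,
        rounding=rounding,
    )


def classify_etc(etc, reached, cutoff: ReferenceCutoff) -> np.ndarray:
    """Vectorized label rule: intact iff reached with ETC strictly below cutoff.

    An ETC exactly at the cutoff, or a censored (never-reached) animal, is
    labelled impaired.
    """
    etc = np.asarray(etc, dtype=float)
    reached = np.asarray(reached, dtype=bool)
    return np.where(reached & (etc < cutoff.cutoff), INTACT, IMPAIRED)


def classify_cohort(results: pd.DataFrame, cutoff: ReferenceCutoff):
    """Label an aged cohort and summarize the resulting subgroups.

    ``results`` is a criterion-results frame (columns ``animal_id``, ``etc``,
    ``reached``). Returns ``(labels, summary)``: per-animal labels with the
    basis recorded, and per-label n / mean ETC / SEM. Classification depends
    only on each animal's own result, so it is order-independent.
    """
    if results.empty:
        raise ValueError("cannot classify an empty cohort")
    labels = results[["animal_id", "etc", "reached"]].copy()
    labels["label"] = classify_etc(labels["etc"], labels["reached"], cutoff)
    labels["cutoff"] = cutoff.cutoff
    summary = (
        labels.groupby("label")["etc"]
        .agg(n="size", mean_etc="mean", sem_etc=lambda v: v.std(ddof=1) / math.sqrt(len(v)))
        .reset_index()
    )
    return labels, summary


def simulate_classification_fractions(
    subgroups,
    cutoff: ReferenceCutoff,
    n_replicates: int = 1000,
    seed=0,
    floor: float = 30.0,
):
    """Monte-Carlo check of the stratified-proportion arithmetic.

    ``subgroups`` is a list of ``(n, mean, sem)`` summaries of per-subgroup
    reversal-ETC distributions; each replicate cohort draws ``n`` values from
    Normal(mean, sem*sqrt(n)) per subgroup (recovering the per-animal SD from
    the summary SEM), floors them at ``floor`` entries (the smallest possible
    ETC for a 30-entry window), and classifies every animal against
    ``cutoff``. Returns ``(impaired_pct, intact_pct)``, mean percentages over
    all replicates.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(n for n, _, _ in subgroups)
    n_impaired = np.zeros(n_replicates)
    for n, mean, sem in subgroups:
        sd = sem * math.sqrt(n)
        draws = np.maximum(rng.normal(mean, sd, size=(n_replicates, n)), floor)
        labels = classify_etc(draws, np.ones_like(draws, dtype=bool), cutoff)
        n_impaired += (labels == IMPAIRED).sum(axis=1)
    impaired_pct = float(np.mean(n_impaired) / n_total * 100.0)
    return impaired_pct, 100.0 - impaired_pct


def zscore_series(values: pd.Series, reference=None) -> pd.Series:
    """Standardize a per-animal metric: (x - mean)/SD with sample SD (n-1).

    ``reference`` optionally supplies the values over which mean and SD are
    taken (e.g. a subgroup); by default the full input. NaNs are ignored in
    the reference and propagate through the output.
    """
    values = pd.Series(values, dtype=float)
    ref = values if reference is None else pd.Series(reference, dtype=float)
    ref = ref.dropna()
    if len(ref) < 2:
        raise ValueError("need at least two defined reference values")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("zero reference SD: z-scores undefined")
    return (values - ref.mean()) / sd


@dataclass
class Embedding3D:
    """Two principal-component coordinates plus a behavioral third axis."""

    coords: pd.DataFrame  # columns pc1, pc2, z3, indexed by sample
    explained_variance_ratio: tuple[float, float]


def augment_embedding(matrix: pd.DataFrame, behavior_z) -> Embedding3D:
    """Top-2 PCA of a samples x features matrix, augmented by a behavior axis.

    Features are centered and decomposed by SVD; component signs are fixed so
    the largest-magnitude loading of each axis is positive. The third
    coordinate is the supplied behavioral z-score, aligned row-for-row with
    the matrix.
    """
    X = np.asarray(matrix, dtype=float)
    z = np.asarray(behavior_z, dtype=float)
    if X.shape[0] != z.shape[0]:
        raise ValueError("behavior_z must align with matrix rows")
    if X.shape[0] < 3:
        raise ValueError("need at least three samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if np.sum(S > 1e-10 * S[0]) < 2:
        raise ValueError("feature matrix has rank < 2; no 2D principal plane")
    for i in range(2):
        lead = np.argmax(np.abs(Vt[i]))
        if Vt[i, lead] < 0:
            U[:, i] *= -1.0
            Vt[i] *= -1.0
    scores = U[:, :2] * S[:2]
    var = S**2
    evr = (float(var[0] / var.sum()), float(var[1] / var.sum()))
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    coords = pd.DataFrame(
        {"pc1": scores[:, 0], "pc2": scores[:, 1], "z3": z}, index=index
    )
    return Embedding3D(coords=coords, explained_variance_ratio=evr)
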