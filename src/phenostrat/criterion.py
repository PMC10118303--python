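"""Moving-window learning criterion and criterion-attainment tables.

An animal "reaches criterion" at the first entry (counted 1-based within the
phase) at which the trailing window of the last ``window`` entries contains at
least ``threshold`` correct choices — by default an 80% success rate over the
trailing 30 entries, so the earliest possible attainment is entry 30. The
window requires a full complement of entries (no partial windows), and the
entry counter and window are reset at the start of the scoped phase:
acquisition performance never leaks into the reversal criterion.

Animals that never attain the criterion are censored at their total number of
phase entries (ETC) and at the phase's final hour (HTC); attainment curves
("survival" tables of proportion reached vs entries or hours) treat them as
never-reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events_io import REVERSAL, SessionSchedule

__all__ = [
    "CriterionRule",
    "CriterionResult",
    "trailing_success_rate",
    "first_attainment",
    "detect_criterion",
    "results_to_frame",
    "survival_table",
]

# absolute slop when comparing a window count against threshold*window, so
# that e.g. 24 correct out of 30 meets a 0.8 threshold exactly
_EPS = 1e-9


@dataclass(frozen=True)
class CriterionRule:
    """Trailing-window success rule: ``window`` entries, ``threshold`` fraction."""

    window: int = 30
    threshold: float = 0.80
    scope: str = REVERSAL

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class CriterionResult:
    """Per-animal attainment result for one (window, threshold, phase) rule.

    ``etc`` is the 1-based entry index within the scoped phase at first
    attainment, or the total number of phase entries if censored; ``htc`` is
    the session hour of the attaining entry, or the phase end hour if
    censored.
    """

    animal_id: str
    reached: bool
    etc: int
    htc: float
    errors_to_criterion: int
    censored: bool


def trailing_success_rate(correct_flags, window: int) -> np.ndarray:
    """Trailing-window success fraction at each entry position.

    Position ``n`` (1-based) gets the fraction of correct entries among
    positions ``n-window+1 .. n``; positions before a full window are NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    flags = np.asarray(correct_flags, dtype=float)
    out = np.full(flags.size, np.nan)
    if flags.size >= window:
        sums = np.convolve(flags, np.ones(window), mode="valid")
        out[window - 1 :] = sums / window
    return out


def first_attainment(correct_flags, window: int, threshold: float):
    """0-based index of the first entry whose trailing window meets threshold.

    Returns ``None`` when the criterion is never met (including streams
    shorter than one full window).
    """
    flags = np.asarray(correct_flags, dtype=float)
    if flags.size < window:
        return None
    sums = np.convolve(flags, np.ones(window), mode="valid")
    hits = np.flatnonzero(sums >= threshold * window - _EPS)
    if hits.size == 0:
        return None
    return int(hits[0]) + window - 1


def detect_criterion(
    events: pd.DataFrame, schedule: SessionSchedule, rule: CriterionRule
) -> CriterionResult:
    """Apply a criterion rule to one animal's events.

    ``events`` must contain a single animal's rows (columns ``animal_id``,
    ``t_seconds``, ``hole``). Entries outside the rule's phase are ignored and
    never influence the window.
    """
    animals = events["animal_id"].unique()
    if len(animals) > 1:
        raise ValueError(f"detect_criterion expects one animal, got {list(animals)}")
    animal_id = str(animals[0]) if len(animals) else "<empty>"

    lo, hi = schedule.phase_interval(rule.scope)
    t_h = events["t_seconds"].to_numpy(dtype=float) / 3600.0
    in_scope = (t_h >= lo) & (t_h < hi)
    t_h = np.sort(t_h[in_scope])
    order = np.argsort(events["t_seconds"].to_numpy()[in_scope], kind="stable")
    holes = events["hole"].to_numpy()[in_scope][order]
    flags = (holes == schedule.correct_hole(rule.scope)).astype(int)

    n = flags.size
    if n == 0:
        return CriterionResult(animal_id, False, 0, float(hi), 0, True)

    idx = first_attainment(flags, rule.window, rule.threshold)
    if idx is None:
        return CriterionResult(
            animal_id, False, n, float(hi), int(n - flags.sum()), True
        )
    etc = idx + 1
    return CriterionResult(
        animal_id,
        True,
        etc,
        float(t_h[idx]),
        int(etc - flags[: etc].sum()),
        False,
    )


def results_to_frame(results, groups=None) -> pd.DataFrame:
    """Tabulate CriterionResults, optionally attaching a group label per animal.

    ``groups`` maps animal_id -> group; omitted animals get group "all".
    """
    rows = []
    for r in results:
        g = "all" if groups is None else groups.get(r.animal_id, "all")
        rows.append(
            {
                "animal_id": r.animal_id,
                "group": g,
                "reached": r.reached,
                "etc": r.etc,
                "htc": r.htc,
                "errors_to_criterion": r.errors_to_criterion,
                "censored": r.censored,
            }
        )
    return pd.DataFrame(rows)


def survival_table(results: pd.DataFrame, axis: str = "entries") -> pd.DataFrame:
    """Step function of proportion-of-animals-reached vs entries or hours.

    ``results`` is a frame from :func:`results_to_frame`. For each group the
    curve steps up at every attainment value; censored animals contribute to
    ``n_at_risk`` but never to the reached proportion, so the curve tops out
    at the fraction that ever reached criterion.
    """
    col = {"entries": "etc", "hours": "htc"}.get(axis)
    if col is None:
        raise ValueError("axis must be 'entries' or 'hours'")
    if results.empty:
        raise ValueError("survival_table requires at least one result")

    out = []
    for group, grp in results.groupby("group", sort=True):
        n = len(grp)
        vals = grp[col].to_numpy(dtype=float)
        reached = grp["reached"].to_numpy(dtype=bool)
        steps = [
            {
                "axis_value": float(v),
                "group": group,
                "n_at_risk": int(np.sum(vals >= v)),
                "proportion_reached": float(np.sum(reached & (vals <= v)) / n),
            }
            for v in np.unique(vals[reached])
        ]
        # terminal point: the curve always extends to the largest observed
        # value (censored included) at the final fraction reached
        max_v = float(vals.max())
        if not steps or steps[-1]["axis_value"] < max_v:
            steps.append(
                {
                    "axis_value": max_v,
                    "group": group,
                    "n_at_risk": int(np.sum(vals >= max_v)),
                    "proportion_reached": float(reached.mean()),
                }
            )
        out.extend(steps)
    return pd.DataFrame(out, columns=["axis_value", "group", "n_at_risk", "proportion_reached"])
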