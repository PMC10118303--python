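"""Learning indices, initial learning rate, cognitive flexibility, extinction.

The learning index over any set of entries is (correct - incorrect) / total,
bounded in [-1, 1]: +1 is perfect performance, 0 chance-symmetric mixing of
correct and incorrect, -1 all errors. It is computed cumulatively from phase
start, independently per hour, or over a fixed hour window. Hour sets with no
entries yield NaN (undefined), never zero — a zero would assert chance-level
performance that absent data cannot support.

Two windowed indices summarize each animal: the *initial learning rate* over
the first 10 h of the acquisition dark phase (hours [3, 13) by default) and
*cognitive flexibility* over the first 10 h of the reversal dark phase (hours
[51, 61)), the period in which the old response must be extinguished and the
new one acquired. Extinction curves resolve the same reversal window into
per-hour percentages of left (previously rewarded), middle, and total error
entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events_io import ACQUISITION, REVERSAL, SessionSchedule

__all__ = [
    "cumulative_learning_index",
    "hourly_learning_index",
    "windowed_learning_index",
    "initial_learning_rate",
    "cognitive_flexibility",
    "extinction_curves",
]


def _index_from_sums(c, i):
    if np.ndim(c) == 0 and not isinstance(c, pd.Series):
        return (float(c) - float(i)) / (c + i) if c + i > 0 else float("nan")
    tot = c + i
    with np.errstate(invalid="ignore", divide="ignore"):
        return (c - i) / tot


def cumulative_learning_index(bins: pd.DataFrame, through_hour: int) -> pd.Series:
    """Per-animal (correct - incorrect)/total from phase start through an hour.

    The phase is the one containing ``through_hour``; hours of the other phase
    never contribute. Animals with zero entries in the range get NaN.
    """
    hours = bins["hour"]
    if through_hour not in set(hours):
        raise ValueError(f"through_hour {through_hour} outside the session")
    phase = bins.loc[hours == through_hour, "phase"].iloc[0]
    sel = bins[(bins["phase"] == phase) & (hours <= through_hour)]
    sums = sel.groupby("animal_id")[["n_correct", "n_incorrect"]].sum()
    return _index_from_sums(sums["n_correct"], sums["n_incorrect"]).rename(
        "cumulative_learning_index"
    )


def hourly_learning_index(bins: pd.DataFrame) -> pd.DataFrame:
    """Independent (per-hour) and cumulative learning-index series.

    Returns one row per (animal, hour) with ``hourly_index`` — the index of
    that hour alone, NaN when the hour has no entries — and
    ``cumulative_index`` — the index over all entries from the start of the
    hour's phase, NaN until the phase has any entries. Both are consistent
    with the same hourly counts: the cumulative value equals the
    entry-weighted aggregation of the hourly values.
    """
    out = bins[["animal_id", "hour", "phase", "n_total"]].copy()
    out["hourly_index"] = _index_from_sums(
        bins["n_correct"].to_numpy(float), bins["n_incorrect"].to_numpy(float)
    )
    g = bins.groupby(["animal_id", "phase"], sort=False)
    cum_c = g["n_correct"].cumsum().to_numpy(float)
    cum_i = g["n_incorrect"].cumsum().to_numpy(float)
    out["cumulative_index"] = _index_from_sums(cum_c, cum_i)
    return out


def windowed_learning_index(bins: pd.DataFrame, hour_window) -> pd.Series:
    """Per-animal learning index over entries in hours ``[start, end)``.

    The window must lie inside a single phase: an index pooled across the
    contingency flip would mix two different correctness definitions.
    """
    start, end = hour_window
    if not start < end:
        raise ValueError("empty hour window")
    sel = bins[(bins["hour"] >= start) & (bins["hour"] < end)]
    if sel.empty:
        raise ValueError(f"window [{start}, {end}) outside the session")
    phases = sel["phase"].unique()
    if len(phases) > 1:
        raise ValueError(
            f"window [{start}, {end}) spans a phase boundary ({sorted(phases)})"
        )
    sums = sel.groupby("animal_id")[["n_correct", "n_incorrect"]].sum()
    return _index_from_sums(sums["n_correct"], sums["n_incorrect"]).rename(
        "windowed_learning_index"
    )


def initial_learning_rate(
    bins: pd.DataFrame, schedule: SessionSchedule, hour_window=None
) -> pd.Series:
    """Learning index over the first acquisition dark window ([3, 13) h default)."""
    window = hour_window or schedule.dark_window(ACQUISITION, length=10)
    return windowed_learning_index(bins, window).rename("initial_learning_rate")


def cognitive_flexibility(
    bins: pd.DataFrame, schedule: SessionSchedule, hour_window=None
) -> pd.Series:
    """Learning index over the first reversal dark window ([51, 61) h default).

    Captures extinction of the acquired response plus relearning of the new
    contingency; impaired animals score near or below zero here.
    """
    window = hour_window or schedule.dark_window(REVERSAL, length=10)
    return windowed_learning_index(bins, window).rename("cognitive_flexibility")


def extinction_curves(
    bins: pd.DataFrame, schedule: SessionSchedule, hour_window=None
) -> pd.DataFrame:
    """Per-hour percent left / middle / error entries over the reversal window.

    Percentages are of that hour's entries; %errors = %left + %middle and
    %right = 100 - %errors. Hours with zero entries are NaN.
    """
    window = hour_window or schedule.dark_window(REVERSAL, length=10)
    start, end = window
    rev_lo, rev_hi = schedule.phase_interval(REVERSAL)
    if not (rev_lo <= start < end <= rev_hi):
        raise ValueError(f"window [{start}, {end}) must lie within the reversal phase")
    sel = bins[(bins["hour"] >= start) & (bins["hour"] < end)].copy()
    tot = sel["n_total"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_left = 100.0 * sel["n_left"].to_numpy(float) / tot
        pct_middle = 100.0 * sel["n_middle"].to_numpy(float) / tot
    out = sel[["animal_id", "hour"]].copy()
    out["pct_left"] = pct_left
    out["pct_middle"] = pct_middle
    out["pct_errors"] = pct_left + pct_middle
    return out.reset_index(drop=True)
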