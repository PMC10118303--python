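"""Synthetic cohort simulator for the 90-h home-cage discrimination/reversal task.

Each simulated animal emits a stream of hole entries over the session. Entry
*timing* follows an inhomogeneous Poisson process with a piecewise-constant
hourly rate (a dark-phase and a light-phase rate), realized per hour as a
Poisson count with uniformly scattered, sorted times — equivalent to an
exponential clock whose rate switches with the light:dark cycle. Entry
*choice* follows a three-alternative model whose correct-choice probability
relaxes exponentially from a naive level ``q0`` toward an asymptote
``q_asym`` with time-constant ``tau`` entries, restarting at the reversal:

    p_correct(n) = q_asym - (q_asym - q0) * exp(-n / tau_phase)

where ``n`` counts entries within the current phase. The residual incorrect
mass is split between the two wrong holes: during acquisition a fraction
``beta_mid`` goes to the middle hole; during reversal a fraction ``w_persev``
goes to the previously rewarded (left) hole, modelling perseveration.

Default profiles for the young, aged-intact and aged-impaired phenotypes are
calibrated so that cohort medians of reversal entries-to-criterion land near
the reference group summaries (see ``docs/methods.md``); impaired animals
learn the reversal far more slowly and direct most errors at the old hole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events_io import ACQUISITION, REVERSAL, EVENT_COLUMNS, SessionSchedule

__all__ = [
    "BehavioralProfile",
    "SimulationConfig",
    "DEFAULT_PROFILES",
    "young_profile",
    "aged_intact_profile",
    "aged_impaired_profile",
    "simulate_entry_stream",
    "simulate_activity_distance",
    "simulate_cohort",
    "generate_feature_matrix",
]


@dataclass(frozen=True)
class BehavioralProfile:
    """Choice-model and entry-rate parameters defining one phenotype.

    ``q0`` is the initial probability of picking the currently correct hole
    (1/3 = chance for three holes), ``q_asym`` the asymptotic level, and
    ``tau_acq``/``tau_rev`` the learning time-constants (entries) for the
    acquisition and reversal phases. ``w_persev`` is the fraction of reversal
    errors directed at the previously correct hole; ``beta_mid`` the fraction
    of acquisition errors directed at the middle hole. Entry rates are mean
    entries/hour in dark vs light. Weight-loss parameters give the percent
    body-weight change over the 90-h session.
    """

    label: str
    q0: float = 1.0 / 3.0
    q_asym: float = 0.85
    tau_acq: float = 350.0
    tau_rev: float = 850.0
    w_persev: float = 0.5
    beta_mid: float = 0.5
    rate_dark: float = 120.0
    rate_light: float = 25.0
    weight_loss_mean_pct: float = 5.5
    weight_loss_sd_pct: float = 4.5
    age_months: float = 6.0

    def __post_init__(self) -> None:
        for name in ("q0", "q_asym", "w_persev", "beta_mid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.q_asym < self.q0:
            raise ValueError("q_asym must be >= q0")
        if not (self.tau_acq > 0 and self.tau_rev > 0):
            raise ValueError("learning time-constants must be positive")
        if not self.rate_dark >= self.rate_light > 0:
            raise ValueError("require rate_dark >= rate_light > 0")

    def tau(self, phase: str) -> float:
        return self.tau_acq if phase == ACQUISITION else self.tau_rev


def young_profile(**overrides) -> BehavioralProfile:
    """Young-adult reference phenotype (fast, stable reversal learning)."""
    return replace(
        BehavioralProfile(
            label="young",
            q_asym=0.85,
            tau_acq=350.0,
            tau_rev=850.0,
            weight_loss_mean_pct=5.5,
            weight_loss_sd_pct=4.5,
            age_months=6.0,
        ),
        **overrides,
    )


def aged_intact_profile(**overrides) -> BehavioralProfile:
    """Aged but cognitively resilient phenotype; performs like young."""
    return replace(
        BehavioralProfile(
            label="aged_intact",
            q_asym=0.85,
            tau_acq=350.0,
            tau_rev=800.0,
            weight_loss_mean_pct=5.3,
            weight_loss_sd_pct=5.6,
            age_months=29.0,
        ),
        **overrides,
    )


def aged_impaired_profile(**overrides) -> BehavioralProfile:
    """Aged-impaired phenotype: slow reversal learning, strong perseveration."""
    return replace(
        BehavioralProfile(
            label="aged_impaired",
            q_asym=0.80,
            tau_acq=450.0,
            tau_rev=3200.0,
            w_persev=0.65,
            weight_loss_mean_pct=6.6,
            weight_loss_sd_pct=5.2,
            age_months=29.0,
        ),
        **overrides,
    )


DEFAULT_PROFILES = {
    "young": young_profile,
    "aged_intact": aged_intact_profile,
    "aged_impaired": aged_impaired_profile,
}


@dataclass
class SimulationConfig:
    """Cohort layout plus schedule, master seed, and reward schedule."""

    profiles: list[tuple[BehavioralProfile, int]]
    schedule: SessionSchedule = field(default_factory=SessionSchedule)
    seed: int = 0
    reward_every_n_correct: int = 1

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("at least one profile required")
        labels = [p.label for p, _ in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate profile labels: {labels}")
        for p, n in self.profiles:
            if n < 1:
                raise ValueError(f"profile {p.label!r}: n_animals must be >= 1")
        if self.reward_every_n_correct < 1:
            raise ValueError("reward_every_n_correct must be >= 1")


def _entry_times(profile: BehavioralProfile, schedule: SessionSchedule, rng) -> np.ndarray:
    hours = np.arange(schedule.session_hours)
    rates = np.where(schedule.is_dark_hour(hours), profile.rate_dark, profile.rate_light)
    counts = rng.poisson(rates)
    pieces = [
        (h + np.sort(rng.random(c))) * 3600.0
        for h, c in zip(hours, counts)
        if c > 0
    ]
    if not pieces:
        return np.empty(0)
    return np.concatenate(pieces)


def _choice_probs(profile: BehavioralProfile, phase: str, n: np.ndarray) -> np.ndarray:
    tau = profile.tau(phase)
    with np.errstate(over="ignore"):
        decay = np.exp(-n / tau) if math.isfinite(tau) else np.ones_like(n, dtype=float)
    return profile.q_asym - (profile.q_asym - profile.q0) * decay


def simulate_entry_stream(
    profile: BehavioralProfile,
    schedule: SessionSchedule,
    seed,
    animal_id: str = "sim",
) -> pd.DataFrame:
    """Simulate one animal's entry events over the whole session.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`. Events are
    returned sorted in time with the phase-entry counter reset at reversal
    onset, as described in the module docstring.
    """
    rng = np.random.default_rng(seed)
    t = _entry_times(profile, schedule, rng)
    holes = np.empty(t.size, dtype=object)
    t_h = t / 3600.0

    for phase in (ACQUISITION, REVERSAL):
        lo, hi = schedule.phase_interval(phase)
        mask = (t_h >= lo) & (t_h < hi)
        m = int(mask.sum())
        if m == 0:
            continue
        n = np.arange(1, m + 1, dtype=float)
        p = _choice_probs(profile, phase, n)
        if phase == ACQUISITION:
            correct, biased, other = (
                schedule.acquisition_hole,
                "middle",
                schedule.reversal_hole,
            )
            frac = profile.beta_mid
        else:
            # perseveration: errors biased toward the previously correct hole
            correct, biased, other = (
                schedule.reversal_hole,
                schedule.acquisition_hole,
                "middle",
            )
            frac = profile.w_persev
        u = rng.random(m)
        holes[mask] = np.where(
            u < p, correct, np.where(u < p + frac * (1.0 - p), biased, other)
        )

    return pd.DataFrame(
        {"animal_id": animal_id, "t_seconds": t, "hole": holes},
        columns=EVENT_COLUMNS,
    )


# Hourly distance-moved distribution (arbitrary length units). Identical for
# every phenotype: the emulated study found no group differences in activity.
_DIST_DARK = (900.0, 90.0)
_DIST_LIGHT = (250.0, 40.0)


def simulate_activity_distance(schedule: SessionSchedule, seed) -> np.ndarray:
    """Hourly distance-moved trace with circadian (dark >> light) modulation."""
    rng = np.random.default_rng(seed)
    dark = schedule.is_dark_hour(np.arange(schedule.session_hours))
    mu = np.where(dark, _DIST_DARK[0], _DIST_LIGHT[0])
    sd = np.where(dark, _DIST_DARK[1], _DIST_LIGHT[1])
    return np.maximum(0.0, rng.normal(mu, sd))


def _pellets_per_hour(
    events: pd.DataFrame, schedule: SessionSchedule, every_n: int
) -> np.ndarray:
    """Pellets dispensed per hour: one per ``every_n``-th correct entry."""
    t_h = events["t_seconds"].to_numpy(dtype=float) / 3600.0
    correct = events["hole"].to_numpy() == schedule.correct_hole_of_hours(t_h)
    cum = np.cumsum(correct)
    rewarded = correct & (cum % every_n == 0)
    hour = np.minimum(t_h.astype(int), schedule.session_hours - 1)
    return np.bincount(hour[rewarded], minlength=schedule.session_hours)


def simulate_cohort(config: SimulationConfig):
    """Simulate a full cohort: events, cohort metadata table, activity traces.

    Returns ``(events, cohort, activity)`` DataFrames. Per-animal randomness is
    spawned deterministically from the master seed, so the same config always
    yields byte-identical outputs regardless of cohort composition order
    changes elsewhere.
    """
    schedule = config.schedule
    n_total = sum(n for _, n in config.profiles)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(n_total)

    events_parts, cohort_rows, activity_rows = [], [], []
    k = 0
    for profile, n_animals in config.profiles:
        for i in range(n_animals):
            animal_id = f"{profile.label}_{i + 1:02d}"
            ev_ss, act_ss, wt_ss = children[k].spawn(3)
            k += 1
            ev = simulate_entry_stream(profile, schedule, ev_ss, animal_id=animal_id)
            events_parts.append(ev)

            wt_rng = np.random.default_rng(wt_ss)
            pre = wt_rng.normal(32.0, 3.0)
            loss = wt_rng.normal(profile.weight_loss_mean_pct, profile.weight_loss_sd_pct)
            cohort_rows.append(
                {
                    "animal_id": animal_id,
                    "group": profile.label,
                    "age_months": profile.age_months,
                    "weight_pre_g": round(pre, 3),
                    "weight_post_g": round(pre * (1.0 - loss / 100.0), 3),
                }
            )

            dist = simulate_activity_distance(schedule, act_ss)
            pellets = _pellets_per_hour(ev, schedule, config.reward_every_n_correct)
            for h in range(schedule.session_hours):
                activity_rows.append(
                    {
                        "animal_id": animal_id,
                        "hour": h,
                        "distance_moved": dist[h],
                        "pellets": int(pellets[h]),
                    }
                )

    events = pd.concat(events_parts, ignore_index=True)
    cohort = pd.DataFrame(cohort_rows)
    activity = pd.DataFrame(activity_rows)
    return events, cohort, activity


def generate_feature_matrix(
    cohort: pd.DataFrame,
    n_features: int,
    effect_size: float,
    seed,
) -> pd.DataFrame:
    """Toy molecular feature matrix with group-dependent mean shifts.

    Rows follow ``cohort`` order (indexed by animal_id); features are standard
    normal. The first-listed group acts as reference; every other group gets
    its own disjoint block of features shifted down by ``effect_size`` SD,
    emulating pathway down-regulation confined to affected subgroups. Blocks
    are orthogonal so distinct groups separate along distinct directions.
    """
    if n_features < 3:
        raise ValueError("n_features must be >= 3")
    rng = np.random.default_rng(seed)
    groups = cohort["group"].to_numpy()
    ordered = list(dict.fromkeys(groups))  # preserves first-appearance order
    shifted = ordered[1:]
    X = rng.standard_normal((len(cohort), n_features))
    if shifted:
        block = max(1, n_features // (2 * len(shifted)))
        for j, g in enumerate(shifted):
            lo, hi = j * block, min((j + 1) * block, n_features)
            X[groups == g, lo:hi] -= effect_size
    return pd.DataFrame(
        X,
        index=pd.Index(cohort["animal_id"], name="animal_id"),
        columns=[f"f{j}" for j in range(n_features)],
    )
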