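import numpy as np
import pandas as pd
import pytest

from phenostrat import simcage
from phenostrat.criterion import CriterionRule, detect_criterion, results_to_frame
from phenostrat.events_io import REVERSAL, SessionSchedule, bin_events_hourly


@pytest.fixture(scope="session")
def schedule():
    return SessionSchedule()


@pytest.fixture(scope="session")
def sim_cohort(schedule):
    """Small three-group simulated cohort shared across test modules.

    Six animals per phenotype at the default profiles, master seed fixed.
    Returns (events, cohort, activity) frames.
    """
    config = simcage.SimulationConfig(
        profiles=[
            (simcage.young_profile(), 6),
            (simcage.aged_intact_profile(), 6),
            (simcage.aged_impaired_profile(), 6),
        ],
        schedule=schedule,
        seed=2024,
    )
    return simcage.simulate_cohort(config)


@pytest.fixture(scope="session")
def sim_bins(sim_cohort, schedule):
    events, _, _ = sim_cohort
    return bin_events_hourly(events, schedule)


@pytest.fixture(scope="session")
def sim_reversal_results(sim_cohort, schedule):
    """Reversal-phase criterion results for the shared cohort, with groups."""
    events, cohort, _ = sim_cohort
    rule = CriterionRule(scope=REVERSAL)
    results = [
        detect_criterion(grp, schedule, rule)
        for _, grp in events.groupby("animal_id", sort=True)
    ]
    return results_to_frame(results, groups=dict(zip(cohort["animal_id"], cohort["group"])))


def make_events(times_hours, holes, animal_id="m1"):
    """Build a minimal event frame from parallel time (hours) and hole lists."""
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "t_seconds": np.asarray(times_hours, dtype=float) * 3600.0,
            "hole": list(holes),
        }
    )
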