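"""Synthetic datasets with the statistical structure the estimators assume.

Two generators stand in for the study's raw field and laboratory data:

* a daily-checked two-treatment foundress-chamber survival experiment across
  two nuptial flights (default 53 + 43 = 96 chambers) with a nest-within-
  flight random effect, competing foundress death, and right censoring;
* an 11-colony nuptial-flight survey where infected colonies carry a
  per-colony alate hitchhiking prevalence in the 2.2%–6.8% range.

Garden failure times are exponential under proportional hazards with a
log-normal nest frailty, then discretised to whole days (ceiling) to mimic
24-hour checks and force tied event times. Foundress death is generated
independently of treatment, consistent with the experiment's finding that
foundress mortality does not differ between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import SURVEY_COLUMNS, SURVIVAL_COLUMNS, validate_survival_records

__all__ = [
    "ExperimentDesign",
    "SurveyDesign",
    "generate_survival_experiment",
    "generate_field_survey",
    "generate_disturbance_flags",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of the synthetic foundress-chamber survival experiment.

    Defaults mirror the laboratory study conditions: two flights of 53 and
    43 chambers, an even split of roach vs no-roach treatments, a true garden
    hazard ratio of 3.36 for roach presence, modest nest-level heterogeneity,
    rare treatment-independent foundress death, and a 60-day follow-up with
    a baseline garden hazard that puts most failures inside the follow-up
    window.
    """

    flights: tuple = ((1, 53), (2, 43))
    nests_per_flight: int = 4
    treatment_ratio: float = 0.5
    baseline_daily_hazard: float = 0.05
    true_log_hr: float = float(np.log(3.36))
    frailty_sd: float = 0.3
    foundress_daily_death_hazard: float = 0.005
    followup_days: int = 60
    disturbance_prob: float = 0.625
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_daily_hazard < 0 or self.foundress_daily_death_hazard < 0:
            raise ValueError("hazards must be >= 0")
        if not 0.0 <= self.treatment_ratio <= 1.0:
            raise ValueError("treatment_ratio must be in [0, 1]")
        if self.followup_days < 1:
            raise ValueError("followup_days must be >= 1")
        if sum(n for _, n in self.flights) < 2:
            raise ValueError("need at least 2 chambers in total")
        if self.nests_per_flight < 1:
            raise ValueError("nests_per_flight must be >= 1")
        if not 0.0 <= self.disturbance_prob <= 1.0:
            raise ValueError("disturbance_prob must be in [0, 1]")


@dataclass(frozen=True)
class SurveyDesign:
    """Design of the synthetic nuptial-flight survey.

    Defaults emulate the field survey: 11 colonies, each infected with
    probability 8/11, several hundred alates sampled per colony, and
    per-colony hitchhiking prevalence uniform on [0.022, 0.068].
    """

    n_colonies: int = 11
    p_colony_infected: float = 8.0 / 11.0
    alates_per_colony: tuple[int, int] = (300, 1200)
    prevalence_range: tuple[float, float] = (0.022, 0.068)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if not 0.0 <= self.p_colony_infected <= 1.0:
            raise ValueError("p_colony_infected must be in [0, 1]")
        lo, hi = self.prevalence_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("prevalence_range must satisfy 0 <= low <= high <= 1")
        a, b = self.alates_per_colony
        if not 1 <= a <= b:
            raise ValueError("alates_per_colony must satisfy 1 <= min <= max")


def _exponential_day(rng: np.random.Generator, hazard: float, size: int) -> np.ndarray:
    """Whole-day event times: exponential draws discretised by ceiling.

    Zero hazard means the event never happens (inf).
    """
    if hazard == 0:
        return np.full(size, np.inf)
    raw = rng.exponential(1.0 / hazard, size=size)
    return np.ceil(raw)


def generate_survival_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Simulate the chamber experiment; seed-deterministic.

    Competing risks are resolved by earliest day; a same-day garden/foundress
    collision is recorded as foundress death (a dead caretaker makes the
    garden effectively dead). Censoring happens at ``followup_days``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    chamber = 0
    for flight_id, n_chambers in design.flights:
        nest_ids = rng.integers(1, design.nests_per_flight + 1, size=n_chambers)
        nest_effects = {
            nest: rng.normal(0.0, design.frailty_sd)
            for nest in range(1, design.nests_per_flight + 1)
        }
        n_roach = int(round(n_chambers * design.treatment_ratio))
        treatments = np.array(["roach"] * n_roach
                              + ["no_roach"] * (n_chambers - n_roach))
        rng.shuffle(treatments)
        for i in range(n_chambers):
            chamber += 1
            treat = treatments[i]
            log_hazard = np.log(design.baseline_daily_hazard) if \
                design.baseline_daily_hazard > 0 else -np.inf
            eta = nest_effects[nest_ids[i]] + (
                design.true_log_hr if treat == "roach" else 0.0
            )
            garden_hazard = (np.exp(log_hazard + eta)
                             if np.isfinite(log_hazard) else 0.0)
            garden_day = _exponential_day(rng, garden_hazard, 1)[0]
            foundress_day = _exponential_day(
                rng, design.foundress_daily_death_hazard, 1)[0]
            first = min(garden_day, foundress_day, design.followup_days + 1)
            if first > design.followup_days:
                day, outcome, died = design.followup_days, "censored", False
            elif foundress_day <= garden_day:
                day, outcome, died = int(foundress_day), "foundress_dead", True
            else:
                day, outcome, died = int(garden_day), "uncaring", False
            disturbed = (bool(rng.random() < design.disturbance_prob)
                         if treat == "roach" else None)
            rows.append({
                "chamber_id": f"ch{chamber:03d}",
                "treatment": treat,
                "flight_id": flight_id,
                "nest_id": f"f{flight_id}n{nest_ids[i]}",
                "day": day,
                "garden_outcome": outcome,
                "foundress_died": died,
                "disturbed": disturbed,
            })
    df = pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
    validate_survival_records(df)
    return df


def generate_field_survey(design: SurveyDesign) -> pd.DataFrame:
    """Simulate the colony survey; seed-deterministic.

    Each colony is infected with probability ``p_colony_infected``; infected
    colonies draw a prevalence uniformly from ``prevalence_range`` and a
    binomial count of roach-bearing alates; uninfected colonies carry none.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.prevalence_range
    a, b = design.alates_per_colony
    rows = []
    for c in range(1, design.n_colonies + 1):
        alates = int(rng.integers(a, b + 1))
        if rng.random() < design.p_colony_infected:
            prev = rng.uniform(lo, hi)
            with_roach = int(rng.binomial(alates, prev))
        else:
            with_roach = 0
        rows.append({
            "colony_id": f"col{c:02d}",
            "site": "site1" if c % 2 else "site2",
            "alates_sampled": alates,
            "alates_with_roach": with_roach,
        })
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def generate_disturbance_flags(n: int, p: float, seed: int) -> np.ndarray:
    """n independent Bernoulli(p) garden-disturbance flags; seed-deterministic."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.random(n) < p
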