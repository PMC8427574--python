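"""Empirical estimation stage: survival endpoints, Kaplan–Meier curves,
contingency tests, exact binomial intervals, and field-survey summaries.

The survival experiment follows foundress chambers checked daily; a garden
"fails" when its foundress stops tending it (uncaring) or dies. Two endpoint
definitions are supported: *combined* (uncaring or foundress death both count
as garden failure) and *uncaring_only* (foundress deaths are right-censored
at the death day, preserving risk sets). The fitted hazard ratio from either
definition converts to the transmission model's virulence ratio via
delta = 1/HR.

The field survey yields the mature-colony infection prevalence V_field
(fraction of sampled colonies with at least one hitchhiking roach among their
alates) and the maximum per-colony alate prevalence, used as the conservative
foundress prevalence J.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cox import CoxPH, CoxResult, cox_fit, delta_from_hr  # noqa: F401 (re-export)

__all__ = [
    "SURVIVAL_COLUMNS",
    "SURVEY_COLUMNS",
    "ENDPOINT_DEFINITIONS",
    "endpoint_events",
    "km_survivorship",
    "chi_square_2x2",
    "proportion_ci",
    "survey_summary",
    "read_survival_csv",
    "read_survey_csv",
    "fit_survival_experiment",
    "cox_fit",
    "delta_from_hr",
]

SURVIVAL_COLUMNS = [
    "chamber_id", "treatment", "flight_id", "nest_id",
    "day", "garden_outcome", "foundress_died", "disturbed",
]
SURVEY_COLUMNS = ["colony_id", "site", "alates_sampled", "alates_with_roach"]
ENDPOINT_DEFINITIONS = ("combined", "uncaring_only")
OUTCOMES = ("uncaring", "foundress_dead", "censored")


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
    validate_survival_records(df)
    return df


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    return df


def validate_survival_records(records: pd.DataFrame) -> None:
    if (records["day"] < 1).any():
        raise ValueError("day must be >= 1 for every chamber")
    bad = ~records["garden_outcome"].isin(OUTCOMES)
    if bad.any():
        raise ValueError(
            f"unknown garden_outcome values: {records.loc[bad, 'garden_outcome'].unique()}"
        )
    dead = records["garden_outcome"] == "foundress_dead"
    if not records.loc[dead, "foundress_died"].astype(bool).all():
        raise ValueError("garden_outcome=foundress_dead requires foundress_died=True")
    no_roach = records["treatment"] == "no_roach"
    if records.loc[no_roach, "disturbed"].notna().any():
        raise ValueError("disturbed flag only applies to roach chambers")


def endpoint_events(
    records: pd.DataFrame, definition: str = "combined"
) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) per chamber under the chosen garden-failure definition.

    combined: uncaring and foundress_dead both count as events.
    uncaring_only: only uncaring counts; foundress deaths are right-censored
    at the death day.
    """
    if definition not in ENDPOINT_DEFINITIONS:
        raise ValueError(
            f"definition must be one of {ENDPOINT_DEFINITIONS}, got {definition!r}"
        )
    if len(records) == 0:
        raise ValueError("no survival records")
    times = records["day"].to_numpy(dtype=float)
    outcome = records["garden_outcome"]
    if definition == "combined":
        event = outcome.isin(["uncaring", "foundress_dead"]).to_numpy()
    else:
        event = (outcome == "uncaring").to_numpy()
    return times, event


def fit_survival_experiment(
    records: pd.DataFrame,
    definition: str = "combined",
    ties_method: str = "breslow",
    frailty: bool = False,
    stratify_by_flight: bool = False,
) -> CoxResult:
    """Endpoint construction + Cox fit in one step (treatment = roach arm).

    With ``frailty=True`` a gamma shared frailty on nest-within-flight is
    fitted; ``stratify_by_flight`` is the simpler fallback with separate
    baseline hazards per flight.
    """
    times, event = endpoint_events(records, definition)
    group = (records["treatment"] == "roach").astype(float).to_numpy()
    frailty_group = None
    strata = None
    if frailty:
        frailty_group = (
            records["flight_id"].astype(str) + "/" + records["nest_id"].astype(str)
        ).to_numpy()
    elif stratify_by_flight:
        strata = records["flight_id"].to_numpy()
    return cox_fit(times, event, group, ties_method=ties_method,
                   frailty_group=frailty_group, strata=strata)


def km_survivorship(times, events, group) -> dict[object, pd.DataFrame]:
    """Per-group Kaplan–Meier curves (product-limit, ties aggregated by day).

    Returns a dict mapping each group label to a DataFrame with columns
    ``day`` and ``survival``; every curve starts at (0, 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    if len(t) == 0:
        raise ValueError("no observations")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    curves = {}
    for label in np.unique(g):
        m = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], event_observed=e[m])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"day": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity_correction: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]].

    Yates continuity correction on by default (matching common statistical
    environments). Returns (statistic, df, upper-tail p).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    x2, p, df, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(x2), int(df), float(p)


def proportion_ci(
    k: int, n: int, method: str = "clopper_pearson", level: float = 0.95
) -> tuple[float, float, float]:
    """Binomial proportion with confidence interval.

    ``clopper_pearson`` gives the exact interval from beta quantiles;
    ``wilson`` and ``wald`` are the usual approximations.
    """
    if not (0 <= k <= n and n >= 1):
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson", "wald": "normal"}
    if method not in sm_method:
        raise ValueError(f"method must be one of {sorted(sm_method)}")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level,
                                      method=sm_method[method])
    return k / n, float(max(lower, 0.0)), float(min(upper, 1.0))


def survey_summary(records: pd.DataFrame) -> dict:
    """Field-survey prevalence summary.

    A colony is infected when at least one sampled alate carries a roach.
    Returns V_field (infected colonies / colonies), per-colony alate
    prevalences, their maximum (the conservative J estimate), and totals.
    Colonies with zero sampled alates are excluded with a warning.
    """
    if len(records) == 0:
        raise ValueError("no survey records")
    df = records.copy()
    zero = df["alates_sampled"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} colonies with zero sampled alates",
            UserWarning, stacklevel=2,
        )
        df = df[~zero]
    if ((df["alates_with_roach"] < 0)
            | (df["alates_with_roach"] > df["alates_sampled"])).any():
        raise ValueError("need 0 <= alates_with_roach <= alates_sampled")
    infected = df["alates_with_roach"] > 0
    per_colony = (df["alates_with_roach"] / df["alates_sampled"]).to_numpy()
    return {
        "V_field": float(infected.mean()),
        "n_colonies": int(len(df)),
        "n_infected": int(infected.sum()),
        "per_colony_prevalence": per_colony,
        "J_max": float(per_colony.max()),
        "total_alates": int(df["alates_sampled"].sum()),
        "total_roaches": int(df["alates_with_roach"].sum()),
    }
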