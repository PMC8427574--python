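"""Discrete-time stochastic cohort simulator of colony founding and death.

Serves as an independent Monte-Carlo check on the deterministic equilibrium
prevalence: each simulated year a fresh cohort of foundresses arrives, a
binomial share of them carries the symbiont, foundresses mature into colonies
with treatment-specific probabilities, inherited infections persist with
probability z, and every standing mature colony dies with probability q.
With a large foundress supply the post-burn-in prevalence fluctuates around
the closed-form V = delta*z/(1/J - 1 + delta).

Rates from :class:`~symvert.transmission.TransmissionParams` are interpreted
as per-year probabilities, so all of s_i, s_u, q must lie in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transmission import TransmissionParams

__all__ = ["SimConfig", "SimResult", "CohortSimulation", "simulate_cohorts",
           "prevalence_distribution"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a cohort simulation run.

    ``annual_foundresses`` foundresses found nests each year; each is
    infected with probability ``J``. ``burn_in`` initial years are discarded
    from all summaries.
    """

    params: TransmissionParams
    annual_foundresses: int = 10_000
    J: float = 0.07
    years: int = 250
    burn_in: int = 50
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.annual_foundresses < 1:
            raise ValueError("annual_foundresses must be >= 1")
        if not self.years > self.burn_in >= 0:
            raise ValueError("need years > burn_in >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.J <= 1.0:
            raise ValueError(f"J must be in [0, 1], got {self.J}")
        for name in ("s_i", "s_u", "q", "z"):
            v = getattr(self.params, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{name}={v} not interpretable as a per-year probability"
                )

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        params = TransmissionParams(**raw.pop("params"))
        return cls(params=params, **raw)


@dataclass
class SimResult:
    """Yearly mature-colony counts per replicate plus prevalence summaries."""

    years: np.ndarray          # year indices, shape (T,)
    M_i: np.ndarray            # int counts, shape (replicates, T)
    M_u: np.ndarray
    burn_in: int
    config: SimConfig

    def post_burn_in_prevalence(self) -> np.ndarray:
        """Replicate-by-year prevalence after burn-in (nan when no colonies)."""
        mi = self.M_i[:, self.burn_in:].astype(float)
        mu = self.M_u[:, self.burn_in:].astype(float)
        total = mi + mu
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, mi / total, np.nan)

    @property
    def v_hat(self) -> float:
        """Post-burn-in mean prevalence across replicates and years."""
        return float(np.nanmean(self.post_burn_in_prevalence()))

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of v_hat.

        Across replicate means when replicates >= 2 (replicates are
        independent); a single replicate falls back to batch means with
        batches of ~3/q years to absorb the autocorrelation induced by
        colony lifetimes of order 1/q.
        """
        prev = self.post_burn_in_prevalence()
        if self.config.replicates >= 2:
            rep_means = np.nanmean(prev, axis=1)
            return float(np.nanstd(rep_means, ddof=1) / np.sqrt(len(rep_means)))
        series = prev[0]
        series = series[~np.isnan(series)]
        batch = max(1, int(round(3.0 / self.config.params.q)))
        n_batches = len(series) // batch
        if n_batches < 2:
            return float("nan")
        means = series[: n_batches * batch].reshape(n_batches, batch).mean(axis=1)
        return float(np.std(means, ddof=1) / np.sqrt(n_batches))

    def counts_frame(self) -> pd.DataFrame:
        """Long-format (replicate, year, M_i, M_u) counts table."""
        reps, T = self.M_i.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(reps), T),
                "year": np.tile(self.years, reps),
                "M_i": self.M_i.ravel(),
                "M_u": self.M_u.ravel(),
            }
        )

    def summary(self) -> dict:
        mean, sd, (lo, hi) = prevalence_distribution(self)
        return {
            "v_hat": self.v_hat,
            "mc_se": self.mc_se,
            "prevalence_sd": sd,
            "prevalence_ci95": [lo, hi],
            "replicates": self.config.replicates,
            "post_burn_in_years": int(self.years[-1] + 1 - self.burn_in),
        }


def simulate_cohorts(config: SimConfig) -> SimResult:
    """Run the cohort simulation; bit-identical output for a fixed seed.

    Within a year, mortality hits the colonies standing at the start of the
    year, then the year's new maturations are added; colonies are thus not
    at risk of dying in their founding year, and the stationary mean count
    of each class is exactly (yearly inflow)/q, mirroring the continuous
    model. The fixed order matters only at O(q) on counts and cancels in
    the prevalence ratio.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    R, T = config.replicates, config.years
    N = config.annual_foundresses

    M_i = np.zeros((R, T), dtype=np.int64)
    M_u = np.zeros((R, T), dtype=np.int64)
    cur_i = np.zeros(R, dtype=np.int64)
    cur_u = np.zeros(R, dtype=np.int64)

    for t in range(T):
        n_inf = rng.binomial(N, config.J, size=R)
        n_uninf = N - n_inf
        matured_inf = rng.binomial(n_inf, p.s_i)
        retained = rng.binomial(matured_inf, p.z)
        matured_uninf = rng.binomial(n_uninf, p.s_u)
        cur_i -= rng.binomial(cur_i, p.q)
        cur_u -= rng.binomial(cur_u, p.q)
        cur_i = cur_i + retained
        cur_u = cur_u + matured_uninf + (matured_inf - retained)
        M_i[:, t] = cur_i
        M_u[:, t] = cur_u

    return SimResult(
        years=np.arange(T), M_i=M_i, M_u=M_u, burn_in=config.burn_in, config=config
    )


def prevalence_distribution(result: SimResult) -> tuple[float, float, tuple[float, float]]:
    """Mean, SD and central 95% interval of post-burn-in prevalence values."""
    prev = result.post_burn_in_prevalence().ravel()
    prev = prev[~np.isnan(prev)]
    if prev.size == 0:
        raise ValueError("prevalence undefined: no years with mature colonies")
    if prev.size < 2:
        raise ValueError("need at least 2 post-burn-in prevalence samples")
    lo, hi = np.percentile(prev, [2.5, 97.5])
    return float(prev.mean()), float(prev.std(ddof=1)), (float(lo), float(hi))


class CohortSimulation:
    """Model-style wrapper: configure once, ``run()`` returns a SimResult."""

    def __init__(self, config: SimConfig):
        self.config = config

    def run(self) -> SimResult:
        return simulate_cohorts(self.config)
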