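"""Synthetic monitoring data: latent trajectories under harvest plus survey observations.

This module generates the three survey data streams the change-in-ratio model
consumes, from a known ("true") stochastic trajectory:

* PRE   — early-summer structure counts, two classes: calves of the year, and a
          composite FY class (adult females plus yearlings of both sexes),
          binomial with detection probability ``p1``;
* POST  — autumn post-harvest structure counts, three classes: calves, females
          (yearling and older), males (yearling and older), binomial with ``p2``;
* TOT   — optional mid-winter total count, Poisson around the post-harvest total
          (optionally thinned to emulate minimum counts that are biased low).

Class-specific detection biases enter multiplicatively on the detection
probability (clipped to [0, 1]), which is how the sensitivity scenarios are
produced. Harvest is treated as reported without error.

Births are simulated explicitly: ``Calf_t ~ Binomial(mothers_{t-1}, phi2 * f)``
(the number of calves alive at the PRE survey), then a 50:50 sex split and
first-summer survival ``phi1`` yield the calf classes of the pre-harvest vector.
This keeps ``phi1`` identifiable exactly as the estimation model intends: PRE
observations condition on births, the autumn vector on survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .demography import (
    CLASSES,
    DemographicRates,
    MothersPool,
    PopulationVector,
    stable_structure,
)

__all__ = [
    "RateRanges",
    "DetectionModel",
    "ProportionalHarvest",
    "SurveyDataset",
    "SimulationTruth",
    "draw_rates",
    "simulate_trajectory",
    "observe_pre",
    "observe_post",
    "observe_tot",
    "make_dataset",
    "simulate_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateRanges:
    """Uniform sampling ranges for the vital rates and initial population size.

    Defaults are the ranges used throughout the simulation studies:
    f in [0.60, 0.95], phi1 in [0.85, 0.95], phi2 in [0.88, 0.95],
    N1 (pre-harvest total in year 1) in [740, 3700].
    """

    f: tuple[float, float] = (0.60, 0.95)
    phi1: tuple[float, float] = (0.85, 0.95)
    phi2: tuple[float, float] = (0.88, 0.95)
    n1: tuple[int, int] = (740, 3700)

    def __post_init__(self) -> None:
        for name in ("f", "phi1", "phi2", "n1"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range for {name} has lower > upper: ({lo}, {hi})")


@dataclass(frozen=True)
class DetectionModel:
    """Detection probabilities and class-specific relative-bias multipliers.

    ``p1`` / ``p2`` may be scalars or per-year arrays. ``p_tot = 1`` means the
    winter total count is an unbiased Poisson sample of the post-harvest total;
    values below one thin the Poisson intensity (minimum counts biased low).
    The ``rel_*`` multipliers scale the detection probability of the named class
    relative to the survey's reference classes (1 = equal detectability);
    effective per-class probabilities are clipped to [0, 1].
    """

    p1: float | np.ndarray = 0.7
    p2: float | np.ndarray = 0.7
    p_tot: float = 1.0
    rel_fy_pre: float = 1.0
    rel_female_post: float = 1.0
    rel_male_post: float = 1.0

    def p1_series(self, n_years: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.p1, dtype=float), (n_years,)).copy()

    def p2_series(self, n_years: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.p2, dtype=float), (n_years,)).copy()


@dataclass(frozen=True)
class ProportionalHarvest:
    """Fixed per-class harvest fractions, rounded down, truncated to availability.

    Defaults give a realistic male-skewed off-take: 10% of calves, 10% of
    females (yearling and older), 20% of males (yearling and older).
    """

    calves: float = 0.10
    females: float = 0.10
    males: float = 0.20

    def __call__(self, n: np.ndarray, year: int) -> np.ndarray:
        frac = np.array(
            [self.calves, self.females, self.females, self.calves, self.males, self.males]
        )
        return np.floor(frac * n).astype(np.int64)


HarvestPolicy = Callable[[np.ndarray, int], np.ndarray]


@dataclass
class SurveyDataset:
    """Aligned annual series of PRE / POST counts, harvest, and optional TOT counts.

    Survey counts are stored as floats so that missing years can be carried as
    NaN; harvest must be complete. ``harvest`` has one row per year in the class
    order ``demography.CLASSES``.
    """

    years: np.ndarray
    pre_calves: np.ndarray
    pre_fy: np.ndarray
    post_calves: np.ndarray
    post_females: np.ndarray
    post_males: np.ndarray
    harvest: np.ndarray
    tot: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        t = self.years.size
        for name in ("pre_calves", "pre_fy", "post_calves", "post_females", "post_males"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (t,):
                raise ValueError(f"{name} must have shape ({t},), got {arr.shape}")
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError(f"{name} contains negative counts")
            setattr(self, name, arr)
        self.harvest = np.asarray(self.harvest, dtype=np.int64)
        if self.harvest.shape != (t, 6):
            raise ValueError(f"harvest must have shape ({t}, 6), got {self.harvest.shape}")
        if np.any(self.harvest < 0):
            raise ValueError("harvest contains negative counts")
        if self.tot is not None:
            self.tot = np.asarray(self.tot, dtype=float)
            if self.tot.shape != (t,):
                raise ValueError(f"tot must have shape ({t},)")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "year": self.years,
            "pre_calves": self.pre_calves,
            "pre_fy": self.pre_fy,
            "post_calves": self.post_calves,
            "post_females": self.post_females,
            "post_males": self.post_males,
        }
        for k, name in enumerate(CLASSES):
            data[f"harvest_{name}"] = self.harvest[:, k]
        if self.tot is not None:
            data["tot"] = self.tot
        return pd.DataFrame(data)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated trajectory (for scoring estimator bias).

    ``n`` and ``x`` are the pre- and post-harvest class matrices (T x 6),
    ``births`` the number of calves alive at each PRE survey, ``f_t`` and
    ``phi1_t`` the per-year rates actually used (constant-rate simulations store
    constant series).
    """

    n: np.ndarray
    x: np.ndarray
    births: np.ndarray
    harvest: np.ndarray
    f_t: np.ndarray
    phi1_t: np.ndarray
    phi2: float
    rates: DemographicRates
    seed: Optional[int] = None
    detection: Optional[DetectionModel] = None

    @property
    def n_years(self) -> int:
        return int(self.n.shape[0])

    def pre_harvest_totals(self) -> np.ndarray:
        return self.n.sum(axis=1)

    def fy_pool(self, t: int) -> int:
        """PRE composite class: adult females + yearlings of both sexes at year t."""
        return int(self.n[t, 1] + self.n[t, 2] + self.n[t, 4])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"year": np.arange(1, self.n_years + 1)}
        for k, name in enumerate(CLASSES):
            data[f"n_{name}"] = self.n[:, k]
        for k, name in enumerate(CLASSES):
            data[f"x_{name}"] = self.x[:, k]
        for k, name in enumerate(CLASSES):
            data[f"harvest_{name}"] = self.harvest[:, k]
        data["births"] = self.births
        data["f"] = self.f_t
        data["phi1"] = self.phi1_t
        data["phi2"] = np.full(self.n_years, self.phi2)
        return pd.DataFrame(data)


def draw_rates(
    ranges: RateRanges, rng: np.random.Generator
) -> tuple[DemographicRates, int]:
    """Draw vital rates uniformly from their ranges and an initial size N1."""
    f = rng.uniform(*ranges.f)
    phi1 = rng.uniform(*ranges.phi1)
    phi2 = rng.uniform(*ranges.phi2)
    n1 = int(rng.integers(ranges.n1[0], ranges.n1[1] + 1))
    return DemographicRates(f=f, phi1=phi1, phi2=phi2), n1


def _initial_post_harvest(init: int, rates: DemographicRates, mothers: MothersPool) -> np.ndarray:
    """Virtual year-0 post-harvest vector whose expected projection totals ``init``."""
    lam, w = stable_structure(rates, mothers=mothers)
    return np.rint(w * init / lam).astype(np.int64)


def simulate_trajectory(
    init: int | PopulationVector,
    rates: DemographicRates,
    harvest_policy: Optional[HarvestPolicy],
    n_years: int,
    rng: np.random.Generator,
    f_t: Optional[np.ndarray] = None,
    phi1_t: Optional[np.ndarray] = None,
    mothers: MothersPool = "yearlings_and_adults",
) -> SimulationTruth:
    """Simulate a latent trajectory of ``n_years`` annual cycles under pulse harvest.

    ``init`` is either the target pre-harvest total in year 1 (the trajectory is
    seeded from the stable class structure at the given rates) or an explicit
    virtual year-0 post-harvest vector. Per-year rate series ``f_t``/``phi1_t``
    override the constant rates when given. A harvest request exceeding
    availability is truncated with a logged warning, never an error.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years")
    f_series = np.full(n_years, rates.f) if f_t is None else np.asarray(f_t, dtype=float)
    phi1_series = (
        np.full(n_years, rates.phi1) if phi1_t is None else np.asarray(phi1_t, dtype=float)
    )
    if f_series.shape != (n_years,) or phi1_series.shape != (n_years,):
        raise ValueError("f_t and phi1_t must have one value per year")
    phi2 = rates.phi2

    if isinstance(init, PopulationVector):
        x_prev = init.to_array()
    else:
        x_prev = _initial_post_harvest(int(init), rates, mothers)

    n = np.zeros((n_years, 6), dtype=np.int64)
    x = np.zeros((n_years, 6), dtype=np.int64)
    births = np.zeros(n_years, dtype=np.int64)
    harvest = np.zeros((n_years, 6), dtype=np.int64)

    for t in range(n_years):
        pool = x_prev[1] + x_prev[2] if mothers == "yearlings_and_adults" else x_prev[2]
        q = phi2 * f_series[t]
        born = rng.binomial(pool, q)
        born_f = rng.binomial(born, 0.5)
        births[t] = born
        n[t, 0] = rng.binomial(born_f, phi1_series[t])
        n[t, 3] = rng.binomial(born - born_f, phi1_series[t])
        n[t, 1] = rng.binomial(x_prev[0], phi2)
        n[t, 4] = rng.binomial(x_prev[3], phi2)
        n[t, 2] = rng.binomial(x_prev[1] + x_prev[2], phi2)
        n[t, 5] = rng.binomial(x_prev[4] + x_prev[5], phi2)

        h = np.zeros(6, dtype=np.int64) if harvest_policy is None else np.asarray(
            harvest_policy(n[t], t), dtype=np.int64
        )
        if np.any(h > n[t]):
            logger.warning("year %d: harvest request exceeds availability; truncated", t + 1)
            h = np.minimum(h, n[t])
        harvest[t] = h
        x[t] = n[t] - h
        x_prev = x[t]

    return SimulationTruth(
        n=n,
        x=x,
        births=births,
        harvest=harvest,
        f_t=f_series,
        phi1_t=phi1_series,
        phi2=phi2,
        rates=rates,
    )


def _clip01(p: float) -> float:
    return float(min(max(p, 0.0), 1.0))


def observe_pre(
    truth: SimulationTruth,
    year: int,
    p1: float,
    rel_fy_pre: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """PRE survey: binomial counts of calves born and of the FY composite class."""
    calves = int(rng.binomial(truth.births[year], _clip01(p1)))
    fy = int(rng.binomial(truth.fy_pool(year), _clip01(p1 * rel_fy_pre)))
    return calves, fy


def observe_post(
    truth: SimulationTruth,
    year: int,
    p2: float,
    rel_female_post: float,
    rel_male_post: float,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """POST survey: binomial counts of calves, females (y+), males (y+) after harvest."""
    xt = truth.x[year]
    calves = int(rng.binomial(xt[0] + xt[3], _clip01(p2)))
    females = int(rng.binomial(xt[1] + xt[2], _clip01(p2 * rel_female_post)))
    males = int(rng.binomial(xt[4] + xt[5], _clip01(p2 * rel_male_post)))
    return calves, females, males


def observe_tot(
    truth: SimulationTruth, year: int, p_tot: float, rng: np.random.Generator
) -> int:
    """Winter total count: Poisson around the (optionally thinned) post-harvest total."""
    intensity = max(p_tot, 0.0) * float(truth.x[year].sum())
    return int(rng.poisson(intensity))


def make_dataset(
    truth: SimulationTruth,
    detection: DetectionModel,
    include_tot: bool,
    rng: np.random.Generator,
) -> SurveyDataset:
    """Observe every year of a trajectory and bundle the result as a SurveyDataset."""
    t = truth.n_years
    p1 = detection.p1_series(t)
    p2 = detection.p2_series(t)
    pre_c = np.zeros(t)
    pre_fy = np.zeros(t)
    post_c = np.zeros(t)
    post_f = np.zeros(t)
    post_m = np.zeros(t)
    tot = np.zeros(t) if include_tot else None
    for k in range(t):
        pre_c[k], pre_fy[k] = observe_pre(truth, k, p1[k], detection.rel_fy_pre, rng)
        post_c[k], post_f[k], post_m[k] = observe_post(
            truth, k, p2[k], detection.rel_female_post, detection.rel_male_post, rng
        )
        if include_tot:
            tot[k] = observe_tot(truth, k, detection.p_tot, rng)
    return SurveyDataset(
        years=np.arange(1, t + 1),
        pre_calves=pre_c,
        pre_fy=pre_fy,
        post_calves=post_c,
        post_females=post_f,
        post_males=post_m,
        harvest=truth.harvest.copy(),
        tot=tot,
    )


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def simulate_study(
    rng: np.random.Generator,
    ranges: RateRanges = RateRanges(),
    n_years: int = 20,
    harvest_policy: Optional[HarvestPolicy] = None,
    detection: Optional[DetectionModel] = None,
    include_tot: bool = True,
    time_varying: bool = False,
    sigma_logit: float = 0.3,
    p_range: tuple[float, float] = (0.5, 0.9),
    mothers: MothersPool = "yearlings_and_adults",
) -> tuple[SimulationTruth, SurveyDataset]:
    """One full replicate of the simulation study: rates, trajectory, observations.

    Rates and the initial size are drawn uniformly from ``ranges``; detection
    probabilities, when not supplied, are drawn uniformly from ``p_range``
    (one constant value per survey, or one per year when ``time_varying``).
    With ``time_varying`` the per-year fecundity and calf survival are drawn
    from logit-normal year effects with scale ``sigma_logit`` around the drawn
    mean rates.
    """
    rates, n1 = draw_rates(ranges, rng)
    if harvest_policy is None:
        harvest_policy = ProportionalHarvest()

    f_t = phi1_t = None
    if time_varying:
        from scipy.special import expit

        f_t = expit(_logit(rates.f) + rng.normal(0.0, sigma_logit, n_years))
        phi1_t = expit(_logit(rates.phi1) + rng.normal(0.0, sigma_logit, n_years))

    truth = simulate_trajectory(
        n1, rates, harvest_policy, n_years, rng, f_t=f_t, phi1_t=phi1_t, mothers=mothers
    )

    if detection is None:
        size = n_years if time_varying else None
        detection = DetectionModel(
            p1=rng.uniform(*p_range, size=size),
            p2=rng.uniform(*p_range, size=size),
        )
    truth.detection = detection
    dataset = make_dataset(truth, detection, include_tot, rng)
    return truth, dataset
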