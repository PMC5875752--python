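"""Age–sex structured demographic bookkeeping for a harvested ungulate population.

The population is tracked in six classes — calf, yearling, adult (>= 2y), each by
sex — with an annual cycle that starts just before the autumn harvest:

* ``N_t``  pre-harvest population vector (calves are ~3 months old),
* ``H_t``  known harvest off-take (a pulse removal),
* ``X_t = N_t - H_t``  post-harvest vector,
* ``N_{t+1}``  produced from ``X_t`` by overwinter survival (``phi2``),
  spring calving (``f`` calves per surviving female; litter size at most one)
  and first-summer calf survival (``phi1``).

The deterministic skeleton is a 6x6 projection matrix; the stochastic analogue
replaces each transition with a binomial draw. The composite recruitment
probability ``R = phi1 * phi2 * f`` is the probability that a female alive just
after harvest in year t contributes a calf to the pre-harvest vector of year t+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "CLASSES",
    "PopulationVector",
    "DemographicRates",
    "OverHarvestError",
    "apply_harvest",
    "build_transition_matrix",
    "expected_transition",
    "project_stochastic",
    "growth_rate",
    "stable_structure",
]

#: Class order used everywhere: females first, calves/yearlings/adults within sex.
CLASSES = ("cF", "yF", "adF", "cM", "yM", "adM")

MothersPool = Literal["yearlings_and_adults", "adults_only"]


class OverHarvestError(ValueError):
    """Raised when a harvest vector removes more animals than a class holds."""


@dataclass(frozen=True)
class PopulationVector:
    """Six non-negative integer counts: calf / yearling / adult by sex.

    Also used for the post-harvest vector ``X_t`` and the harvest vector ``H_t``.
    """

    cF: int
    yF: int
    adF: int
    cM: int
    yM: int
    adM: int

    def __post_init__(self) -> None:
        for name in CLASSES:
            value = getattr(self, name)
            if value != int(value):
                raise ValueError(f"class {name!r} must be integer-valued, got {value!r}")
            if value < 0:
                raise ValueError(f"class {name!r} must be non-negative, got {value!r}")
            object.__setattr__(self, name, int(value))

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "PopulationVector":
        values = list(arr)
        if len(values) != 6:
            raise ValueError(f"expected 6 classes, got {len(values)}")
        return cls(*values)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in CLASSES], dtype=np.int64)

    def total(self) -> int:
        return int(self.to_array().sum())

    def __getitem__(self, key: str | int) -> int:
        if isinstance(key, str):
            return int(getattr(self, key))
        return int(getattr(self, CLASSES[key]))


@dataclass(frozen=True)
class DemographicRates:
    """Vital rates: fecundity ``f``, calf summer survival ``phi1``, annual survival ``phi2``.

    ``f`` is the number of calves per female alive just prior to calving (litter
    size at most one, hence f <= 1); ``phi1`` covers the pre-harvest survey to the
    post-harvest survey; ``phi2`` covers post-harvest in year t to pre-harvest in
    year t+1 and is shared across all age–sex classes.
    """

    f: float
    phi1: float
    phi2: float

    def __post_init__(self) -> None:
        # f = 0 (no reproduction) and phi = 1 (no mortality) are degenerate but
        # legal: they give the deterministic limits used to validate projections.
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        for name in ("phi1", "phi2"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")

    @property
    def recruitment(self) -> float:
        """Composite recruitment probability R = phi1 * phi2 * f."""
        return self.phi1 * self.phi2 * self.f


def apply_harvest(
    n: PopulationVector, h: PopulationVector, year: int | None = None
) -> PopulationVector:
    """Remove the harvest pulse: ``X = N - H`` componentwise.

    Raises :class:`OverHarvestError` naming the offending class (and year, if
    given) when any class would go negative.
    """
    for name in CLASSES:
        if h[name] > n[name]:
            where = f" in year {year}" if year is not None else ""
            raise OverHarvestError(
                f"harvest of class {name!r}{where} exceeds availability "
                f"({h[name]} > {n[name]})"
            )
    return PopulationVector(*(n[k] - h[k] for k in CLASSES))


def build_transition_matrix(
    rates: DemographicRates, mothers: MothersPool = "yearlings_and_adults"
) -> np.ndarray:
    """6x6 projection matrix A mapping the post-harvest vector X_t to E[N_{t+1}].

    Entry ``A[j, i]`` is the expected contribution of one class-``i`` animal at
    post-harvest time t to class ``j`` at pre-harvest time t+1. Recruitment rows
    (calf-F, calf-M) carry ``phi2*phi1*f/2`` in the female source columns;
    survival transitions carry ``phi2``.

    ``mothers`` selects whether yearling females (adults by next calving) are
    credited as mothers alongside adult females, or adult females only.
    """
    f, phi1, phi2 = rates.f, rates.phi1, rates.phi2
    recruit = phi2 * phi1 * f / 2.0
    a = np.zeros((6, 6), dtype=float)
    mother_cols = (1, 2) if mothers == "yearlings_and_adults" else (2,)
    for col in mother_cols:
        a[0, col] = recruit  # cF <- female stock
        a[3, col] = recruit  # cM <- female stock
    a[1, 0] = phi2  # yF <- cF
    a[2, 1] = phi2  # adF <- yF
    a[2, 2] = phi2  # adF <- adF
    a[4, 3] = phi2  # yM <- cM
    a[5, 4] = phi2  # adM <- yM
    a[5, 5] = phi2  # adM <- adM
    return a


def expected_transition(
    x: PopulationVector | np.ndarray,
    rates: DemographicRates,
    mothers: MothersPool = "yearlings_and_adults",
) -> np.ndarray:
    """Expected pre-harvest vector next year, ``E[N_{t+1} | X_t] = A @ X_t``."""
    arr = x.to_array() if isinstance(x, PopulationVector) else np.asarray(x, dtype=float)
    return build_transition_matrix(rates, mothers=mothers) @ arr


def project_stochastic(
    x: PopulationVector,
    rates: DemographicRates,
    rng: np.random.Generator,
    mothers: MothersPool = "yearlings_and_adults",
) -> PopulationVector:
    """One stochastic projection step: binomial survival and recruitment draws.

    Yearlings of each sex are binomial survivors of that sex's calves; adults are
    binomial survivors of the yearling+adult pool; calves of each sex are an
    independent ``Binomial(mother pool, R/2)`` draw (the two sexes are not
    constrained to share a litter; see the simulate module for the coupled
    birth-process variant used when generating survey data).
    """
    phi2, recruit = rates.phi2, rates.recruitment
    pool = x.yF + x.adF if mothers == "yearlings_and_adults" else x.adF
    return PopulationVector(
        cF=rng.binomial(pool, recruit / 2.0),
        yF=rng.binomial(x.cF, phi2),
        adF=rng.binomial(x.yF + x.adF, phi2),
        cM=rng.binomial(pool, recruit / 2.0),
        yM=rng.binomial(x.cM, phi2),
        adM=rng.binomial(x.yM + x.adM, phi2),
    )


def growth_rate(totals: Sequence[float] | np.ndarray) -> float:
    """Geometric-mean annual growth rate of a series of positive annual totals.

    ``lambda = (totals[-1] / totals[0]) ** (1 / (T - 1))`` — equivalently the
    geometric mean of the year-on-year ratios.
    """
    arr = np.asarray(totals, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("growth_rate needs at least two annual totals")
    if np.any(arr <= 0):
        raise ValueError("growth_rate requires strictly positive totals")
    return float((arr[-1] / arr[0]) ** (1.0 / (arr.size - 1)))


def stable_structure(
    rates: DemographicRates, mothers: MothersPool = "yearlings_and_adults"
) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and stable class distribution of the projection matrix.

    Returns ``(lambda, w)`` with ``w`` normalised to sum to one. With zero
    harvest this is the long-run deterministic growth rate and structure.
    """
    a = build_transition_matrix(rates, mothers=mothers)
    eigvals, eigvecs = np.linalg.eig(a)
    k = int(np.argmax(eigvals.real))
    w = np.abs(eigvecs[:, k].real)
    return float(eigvals[k].real), w / w.sum()
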