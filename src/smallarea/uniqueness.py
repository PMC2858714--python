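"""Equivalence classes, sample uniqueness and population-uniqueness estimation.

An *equivalence class* is the set of records in an area sharing one exact
combination of values on the quasi-identifiers of a model; a class of size
one is a *unique* record.  When the data at hand are a sample (the long-form
census is a 20% simple random sample of the population), sample uniqueness
overstates nothing about population uniqueness by itself: a sample unique
may sit inside a large population class.  The Zayatz estimator bridges the
gap by combining the sample class-size spectrum with the probability that a
population class of size ``j`` contributes a sample unique under the
subsampling model.

Notation used below: ``f_j`` is the number of sample equivalence classes of
exactly ``j`` records, ``F`` the (unknown) population size of a class,
``f`` its observed sample size, ``p`` the sampling fraction and ``N`` the
area population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import (
    DataValidationError,
    ParameterError,
    SchemeError,
    UndefinedResultError,
)
from .schemes import QidModel

__all__ = [
    "RecordTable",
    "EquivalenceSpectrum",
    "UniquenessEstimate",
    "equivalence_classes",
    "sample_uniqueness",
    "zayatz_population_uniqueness",
    "pigeonhole_flag",
    "expected_nonunique_uniform",
    "threshold_indicators",
    "estimate_area_uniqueness",
]


@dataclass
class RecordTable:
    """Person-level categorical microdata: one row per person.

    ``df`` must contain ``area_col`` (a text area code, e.g. an FSA) plus one
    column per quasi-identifier.  ``sampling_fraction`` is the fraction of
    the underlying population the table represents (1.0 for a full
    population, 0.2 for a long-form-style sample).
    """

    df: pd.DataFrame
    area_col: str = "area"
    sampling_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.area_col not in self.df.columns:
            raise DataValidationError(f"missing area column {self.area_col!r}")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ParameterError(
                f"sampling_fraction must be in (0, 1], got {self.sampling_fraction}"
            )
        missing = self.df[self.area_col].isna()
        if missing.any():
            rows = list(np.flatnonzero(missing.to_numpy())[:10])
            raise DataValidationError(f"missing area codes at rows {rows}")

    @property
    def areas(self) -> list[str]:
        return sorted(self.df[self.area_col].unique())

    def area_records(self, area: str) -> pd.DataFrame:
        return self.df[self.df[self.area_col] == area]


@dataclass(frozen=True)
class EquivalenceSpectrum:
    """Class-size frequency spectrum: ``f[j]`` classes of exactly ``j`` records."""

    f: Mapping[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "f", {int(j): int(c) for j, c in self.f.items() if c > 0}
        )
        if any(j < 1 for j in self.f):
            raise ParameterError("class sizes must be >= 1")

    @property
    def n_records(self) -> int:
        return sum(j * c for j, c in self.f.items())

    @property
    def n_classes(self) -> int:
        return sum(self.f.values())

    @property
    def n_uniques(self) -> int:
        """Number of sample uniques, f_1."""
        return self.f.get(1, 0)


@dataclass(frozen=True)
class UniquenessEstimate:
    """Per (area x qid-model) uniqueness summary with threshold indicators."""

    area: str
    model_id: str
    sample_uniqueness: float
    est_population_uniqueness: float
    I05: int
    I20: int
    pop_size: int

    def __post_init__(self) -> None:
        for name in ("sample_uniqueness", "est_population_uniqueness"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be a proportion, got {v}")


def equivalence_classes(
    records: RecordTable | pd.DataFrame,
    model: QidModel | Sequence[str],
    area: str | None = None,
    *,
    area_col: str = "area",
) -> EquivalenceSpectrum:
    """Compute the sample class-size spectrum for one area and model.

    Classes are exact value-tuples over the model's member columns.  Missing
    values form their own category, so two records that are both missing on a
    member still fall in the same class (conservative: distinguishability is
    preserved).
    """
    if isinstance(records, RecordTable):
        df, area_col = records.df, records.area_col
    else:
        df = records
    members = list(model.members) if isinstance(model, QidModel) else list(model)
    absent = [m for m in members if m not in df.columns]
    if absent:
        raise SchemeError(f"model members not present as columns: {absent}")
    if area is not None:
        if area_col not in df.columns:
            raise DataValidationError(f"missing area column {area_col!r}")
        df = df[df[area_col] == area]
        if df.empty:
            raise UndefinedResultError(f"area {area!r} has no records")
    sizes = df.groupby(members, dropna=False, observed=True).size()
    return EquivalenceSpectrum(f=sizes.value_counts().to_dict())


def sample_uniqueness(spectrum: EquivalenceSpectrum) -> float:
    """Proportion of sample records that are unique: f_1 / n_records."""
    n = spectrum.n_records
    if n < 1:
        raise UndefinedResultError("sample uniqueness undefined for an empty area")
    return spectrum.n_uniques / n


def zayatz_population_uniqueness(
    spectrum: EquivalenceSpectrum,
    sampling_fraction: float,
    population_size: int,
    *,
    subsampling: str = "binomial",
) -> float:
    """Estimate the proportion of population uniques from a sample spectrum.

    The estimator proceeds in three steps:

    1. estimate the population class-size distribution naively from the
       sample spectrum, ``P(F=j) ~ f_j / sum_k f_k``;
    2. under binomial subsampling at fraction ``p``, a class of population
       size ``j`` yields a sample unique with probability
       ``P(f=1 | F=j) = j * p * (1-p)**(j-1)``; Bayes' rule then gives the
       probability that a sample unique is a population unique,
       ``P(F=1 | f=1)``;
    3. the expected number of population uniques is the number of sample
       uniques that are truly population uniques scaled up by the per-class
       detection probability ``P(f=1 | F=1) = p``:
       ``f_1 * P(F=1|f=1) / p``.

    The result is divided by ``population_size`` and clipped to [0, 1].
    At ``p = 1`` the estimate reduces to the sample uniqueness.

    Parameters
    ----------
    subsampling:
        ``"binomial"`` (default) or ``"hypergeometric"``, which replaces
        step 2 with the exact without-replacement probability for a sample
        of ``round(p * N)`` records out of ``N``.
    """
    p = float(sampling_fraction)
    N = int(population_size)
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"sampling fraction must be in (0, 1], got {p}")
    if N < spectrum.n_records:
        raise ParameterError(
            f"population size {N} smaller than sample size {spectrum.n_records}"
        )
    f1 = spectrum.n_uniques
    if f1 == 0:
        return 0.0

    js = np.array(sorted(spectrum.f), dtype=float)
    fj = np.array([spectrum.f[int(j)] for j in js], dtype=float)
    p_F = fj / fj.sum()
    if subsampling == "binomial":
        detect = js * p * (1.0 - p) ** (js - 1.0)
    elif subsampling == "hypergeometric":
        n_draw = max(1, round(p * N))
        detect = hypergeom.pmf(1, N, js.astype(int), n_draw)
    else:
        raise ParameterError(f"unknown subsampling model {subsampling!r}")

    denom = float(np.sum(p_F * detect))
    if denom <= 0.0:  # only possible at p == 1 with no singleton class
        return 0.0
    post_unique = float(p_F[js == 1.0][0] * detect[js == 1.0][0] / denom)
    est_uniques = f1 * post_unique / p
    return float(min(1.0, max(0.0, est_uniques / N)))


def pigeonhole_flag(pop_size: int, max_combs: int) -> tuple[bool, int]:
    """Sweeney-style drawer-principle check.

    Distributing ``N`` people over ``k`` possible quasi-identifier
    combinations guarantees some combination holds at least ``ceil(N/k)``
    people.  If ``N <= k`` a unique individual is possible in every
    allocation, so the area is flagged as likely containing a unique.

    Returns ``(flag, ceil(N/k))``.
    """
    N, k = int(pop_size), int(max_combs)
    if N < 1 or k < 1:
        raise ParameterError("pop_size and max_combs must be >= 1")
    return N <= k, math.ceil(N / k)


def expected_nonunique_uniform(pop_size: int, max_combs: int) -> float:
    """Expected fraction of non-unique individuals under uniform allocation.

    If each of ``N`` individuals independently lands in one of ``k`` equally
    likely combinations, an individual shares its class with someone else
    with probability ``1 - (1 - 1/k)**(N-1)``.  For N=15, k=48 this is about
    26%, quantifying how much the drawer-principle flag overstates risk.
    """
    N, k = int(pop_size), int(max_combs)
    if N < 1 or k < 1:
        raise ParameterError("pop_size and max_combs must be >= 1")
    if N == 1:
        return 0.0
    return 1.0 - (1.0 - 1.0 / k) ** (N - 1)


def threshold_indicators(estimate: float) -> tuple[int, int]:
    """Binary indicators that estimated uniqueness exceeds 5% / 20% (strict)."""
    if not (0.0 <= estimate <= 1.0):
        raise ParameterError(f"estimate must be a proportion, got {estimate}")
    return int(estimate > 0.05), int(estimate > 0.20)


def estimate_area_uniqueness(
    records: RecordTable,
    model: QidModel,
    area: str,
    population_size: int,
    *,
    subsampling: str = "binomial",
) -> UniquenessEstimate:
    """Full per-area pipeline: spectrum -> sample and estimated uniqueness -> flags."""
    spectrum = equivalence_classes(records, model, area)
    s_uniq = sample_uniqueness(spectrum)
    est = zayatz_population_uniqueness(
        spectrum,
        records.sampling_fraction,
        population_size,
        subsampling=subsampling,
    )
    i05, i20 = threshold_indicators(est)
    return UniquenessEstimate(
        area=area,
        model_id=model.model_id,
        sample_uniqueness=s_uniq,
        est_population_uniqueness=est,
        I05=i05,
        I20=i20,
        pop_size=int(population_size),
    )
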