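"""Synthetic area-structured categorical populations with known ground truth.

The generator emulates the structure of FSA-level census microdata: a set
of areas with log-uniform population sizes, individuals carrying
categorical quasi-identifier values, and a within-area simple random
sample (default 20%, the long-form sampling fraction) playing the role of
the observed data.  Because the full population is generated, the true
population uniqueness of every (area x qid-model) pair is available by
exact counting, which makes every estimator and model in the package
testable without any external dataset.

Category marginals default to Zipf(1.2) rather than uniform: real census
categories are heavily skewed, and skew is what produces the unbalanced
high-uniqueness indicator regime the risk models are built for.  Optional
latent classes induce dependence between variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .schemes import QidModel, QidScheme, default_scheme
from .uniqueness import (
    RecordTable,
    equivalence_classes,
    sample_uniqueness,
    threshold_indicators,
    zayatz_population_uniqueness,
)

__all__ = ["PopulationSpec", "SyntheticPopulation", "generate_population",
           "build_modeling_table", "true_uniqueness"]


@dataclass
class PopulationSpec:
    """Parameters of a synthetic population.

    ``category_dist`` is ``"zipf"`` (rank-frequency ``p_i ~ i**-s`` with
    exponent ``zipf_s``), ``"uniform"``, or a mapping variable name ->
    explicit probability vector.  ``latent_classes``/``latent_weights``
    switch on a finite-mixture dependence structure: each latent class uses
    its own (seeded, permuted) category distributions.
    """

    n_areas: int = 30
    pop_size_range: tuple[int, int] = (200, 78_457)
    scheme: QidScheme = field(default_factory=default_scheme)
    category_dist: str | Mapping[str, Sequence[float]] = "zipf"
    zipf_s: float = 1.2
    latent_classes: int | None = None
    latent_weights: Sequence[float] | None = None
    sampling_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pop_size_range
        if lo < 1 or hi < lo:
            raise ParameterError(f"invalid pop_size_range {self.pop_size_range}")
        if self.n_areas < 1:
            raise ParameterError("n_areas must be >= 1")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ParameterError("sampling_fraction must be in (0, 1]")
        if isinstance(self.category_dist, str):
            if self.category_dist not in ("zipf", "uniform"):
                raise ParameterError(
                    f"unknown category_dist {self.category_dist!r}"
                )
            if self.category_dist == "zipf" and not (self.zipf_s > 0):
                raise ParameterError(f"zipf exponent must be > 0, got {self.zipf_s}")
        if self.latent_classes is not None:
            if self.latent_classes < 1:
                raise ParameterError("latent_classes must be >= 1")
            if self.latent_weights is not None:
                w = np.asarray(self.latent_weights, dtype=float)
                if len(w) != self.latent_classes or not np.isclose(w.sum(), 1.0):
                    raise ParameterError("latent_weights must sum to 1 per class")

    def base_probs(self, name: str) -> np.ndarray:
        """Category probability vector for one variable."""
        k = self.scheme[name].n_categories
        if isinstance(self.category_dist, Mapping):
            p = np.asarray(self.category_dist[name], dtype=float)
            if len(p) != k or not np.isclose(p.sum(), 1.0) or (p < 0).any():
                raise ParameterError(f"explicit probabilities invalid for {name!r}")
            return p
        if self.category_dist == "uniform":
            return np.full(k, 1.0 / k)
        ranks = np.arange(1, k + 1, dtype=float)
        p = ranks ** -self.zipf_s
        return p / p.sum()


@dataclass
class SyntheticPopulation:
    """A generated full population, its sample, and area population counts."""

    population: RecordTable
    sample: RecordTable
    pop_counts: pd.Series  # area -> N
    spec: PopulationSpec

    def true_uniqueness(self, model: QidModel | Sequence[str], area: str) -> float:
        """Exact population uniqueness of one area under one model."""
        return true_uniqueness(self.population, model, area)

    def truth_table(self, models: Sequence[QidModel]) -> pd.DataFrame:
        """Exact-count uniqueness for every (area x model) pair."""
        rows = []
        for area in self.pop_counts.index:
            pop_df = self.population.area_records(area)
            for m in models:
                spec = equivalence_classes(pop_df, m)
                rows.append(
                    {
                        "area": area,
                        "model_id": m.model_id,
                        "true_uniqueness": sample_uniqueness(spec),
                    }
                )
        return pd.DataFrame(rows)


def true_uniqueness(
    population: RecordTable, model: QidModel | Sequence[str], area: str
) -> float:
    """Ground-truth uniqueness: exact proportion of population uniques."""
    return sample_uniqueness(equivalence_classes(population, model, area))


def _area_rng(seed: int, area_index: int) -> np.random.Generator:
    # independent stream per area: adding/removing areas never perturbs others
    return np.random.default_rng([int(seed), int(area_index)])


def generate_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Generate a population and its within-area simple random sample.

    Area sizes are drawn log-uniformly within ``pop_size_range``; each
    individual's quasi-identifier values are drawn independently per
    variable (or conditionally on a latent class when dependence is
    requested).  Deterministic under ``spec.seed``.
    """
    rng_sizes = np.random.default_rng([spec.seed, 987_654_321])
    lo, hi = spec.pop_size_range
    sizes = np.exp(
        rng_sizes.uniform(np.log(lo), np.log(hi + 1), size=spec.n_areas)
    ).astype(int)
    sizes = np.clip(sizes, lo, hi)

    var_names = list(spec.scheme.names)
    base = {name: spec.base_probs(name) for name in var_names}

    # per-latent-class distributions: seeded permutations of the base vector
    class_probs: list[dict[str, np.ndarray]] | None = None
    weights = None
    if spec.latent_classes is not None:
        rng_lat = np.random.default_rng([spec.seed, 192_837_465])
        class_probs = []
        for _ in range(spec.latent_classes):
            class_probs.append(
                {name: rng_lat.permutation(p) for name, p in base.items()}
            )
        weights = (
            np.full(spec.latent_classes, 1.0 / spec.latent_classes)
            if spec.latent_weights is None
            else np.asarray(spec.latent_weights, dtype=float)
        )

    pop_frames = []
    sample_frames = []
    area_codes = [f"A{i:03d}" for i in range(spec.n_areas)]
    for i, (area, n) in enumerate(zip(area_codes, sizes)):
        rng = _area_rng(spec.seed, i)
        cols: dict[str, np.ndarray] = {"area": np.full(n, area)}
        if class_probs is None:
            for name in var_names:
                cols[name] = rng.choice(len(base[name]), size=n, p=base[name])
        else:
            z = rng.choice(len(class_probs), size=n, p=weights)
            for name in var_names:
                vals = np.empty(n, dtype=int)
                for c, probs in enumerate(class_probs):
                    mask = z == c
                    vals[mask] = rng.choice(
                        len(probs[name]), size=int(mask.sum()), p=probs[name]
                    )
                cols[name] = vals
        frame = pd.DataFrame(cols)
        pop_frames.append(frame)
        n_sample = max(1, round(spec.sampling_fraction * n))
        take = np.sort(rng.choice(n, size=n_sample, replace=False))
        sample_frames.append(frame.iloc[take])

    population = pd.concat(pop_frames, ignore_index=True)
    sample = pd.concat(sample_frames, ignore_index=True)
    counts = pd.Series(sizes, index=pd.Index(area_codes, name="area"), name="population")
    return SyntheticPopulation(
        population=RecordTable(population, sampling_fraction=1.0),
        sample=RecordTable(sample, sampling_fraction=spec.sampling_fraction),
        pop_counts=counts,
        spec=spec,
    )


def build_modeling_table(
    synth: SyntheticPopulation,
    models: Sequence[QidModel],
    *,
    mode: str = "estimate",
    subsampling: str = "binomial",
) -> pd.DataFrame:
    """One row per (area x model): POP, MaxCombs and uniqueness indicators.

    ``mode="estimate"`` derives the indicators from the Zayatz estimate on
    the sample (the realistic pipeline); ``mode="oracle"`` uses exact
    population uniqueness (for estimator-quality studies).
    """
    if mode not in ("estimate", "oracle"):
        raise ParameterError(f"mode must be 'estimate' or 'oracle', got {mode!r}")
    rows = []
    for area, n_pop in synth.pop_counts.items():
        sample_df = synth.sample.area_records(area)
        pop_df = synth.population.area_records(area) if mode == "oracle" else None
        for m in models:
            if mode == "estimate":
                spec = equivalence_classes(sample_df, m)
                est = zayatz_population_uniqueness(
                    spec,
                    synth.spec.sampling_fraction,
                    int(n_pop),
                    subsampling=subsampling,
                )
            else:
                est = sample_uniqueness(equivalence_classes(pop_df, m))
            i05, i20 = threshold_indicators(est)
            rows.append(
                {
                    "area": area,
                    "model_id": m.model_id,
                    "pop": int(n_pop),
                    "max_combs": int(m.max_combs),
                    "uniqueness": est,
                    "I05": i05,
                    "I20": i20,
                }
            )
    return pd.DataFrame(rows)
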