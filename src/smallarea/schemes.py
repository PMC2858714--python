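"""Quasi-identifier schemes and quasi-identifier model enumeration.

A *quasi-identifier* (qid) is a variable an intruder could use, in
combination with others, to re-identify an individual: age, gender,
ethnicity, marital status and so on.  A *quasi-identifier model* is a
subset of 2-5 such variables; its ``MaxCombs`` value is the maximum number
of equivalence classes it can induce, i.e. the product of the variables'
response-category counts.  MaxCombs, together with area population size,
is the predictor that drives the disclosure-risk models in
:mod:`smallarea.risk_model`.

The default scheme mirrors the variables of the Canadian 2001 long-form
census as used for small-area risk assessment: 11 declared variables that
collapse to 8 distinct qids once the four ethnicity-related variables
(language spoken at home, ethnic origin, religious denomination, visible
minority status) are treated as variants of one generic ethnicity
variable.  Enumerating every 2-5 variable model that contains at least
one of the high-utility qids (age, gender), with the generic ethnicity
variable expanded into its four concrete variants, yields 358 models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .errors import ConfigurationError, SchemeError

__all__ = [
    "ETHNICITY_PLACEHOLDER",
    "QuasiIdentifier",
    "QidScheme",
    "QidModel",
    "default_scheme",
    "max_combs",
    "enumerate_models",
]

#: Name of the generic ethnicity variable used during enumeration.  It never
#: appears in an emitted model; every occurrence is expanded into the scheme's
#: concrete ethnicity variants.
ETHNICITY_PLACEHOLDER = "ethnicity"

_UTILITY_CLASSES = ("high_utility", "sensitive")


@dataclass(frozen=True)
class QuasiIdentifier:
    """A single categorical quasi-identifier.

    Parameters
    ----------
    name:
        Variable name, unique within a scheme.
    n_categories:
        Number of response categories (>= 2).
    utility_class:
        ``"high_utility"`` for variables of high utility to an intruder
        (age and gender in the default scheme), ``"sensitive"`` otherwise.
    ethnicity_group_member:
        Whether the variable belongs to the ethnicity variant group.
    """

    name: str
    n_categories: int
    utility_class: str = "sensitive"
    ethnicity_group_member: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemeError("quasi-identifier name must be non-empty")
        if int(self.n_categories) < 2:
            raise SchemeError(
                f"{self.name!r}: n_categories must be >= 2, got {self.n_categories}"
            )
        if self.utility_class not in _UTILITY_CLASSES:
            raise SchemeError(
                f"{self.name!r}: utility_class must be one of {_UTILITY_CLASSES}, "
                f"got {self.utility_class!r}"
            )


@dataclass(frozen=True)
class QidScheme:
    """A declared set of quasi-identifiers plus the ethnicity variant group.

    ``ethnicity_variants`` lists, in order, the concrete variables that stand
    in for the generic ethnicity variable during model enumeration (language,
    ethnic origin, religion, visible minority in the default scheme).
    """

    variables: tuple[QuasiIdentifier, ...]
    ethnicity_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "ethnicity_variants", tuple(self.ethnicity_variants))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemeError(f"duplicate variable names in scheme: {dupes}")
        if ETHNICITY_PLACEHOLDER in names:
            raise SchemeError(
                f"{ETHNICITY_PLACEHOLDER!r} is reserved for the generic ethnicity "
                "placeholder and cannot be a declared variable"
            )
        missing = [v for v in self.ethnicity_variants if v not in names]
        if missing:
            raise ConfigurationError(
                f"ethnicity variants not declared in scheme: {missing}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> QuasiIdentifier:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemeError(f"unknown quasi-identifier: {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def high_utility_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.utility_class == "high_utility")

    def max_combs(self, member_names: Iterable[str]) -> int:
        """MaxCombs for a set of member variable names from this scheme."""
        return max_combs([self[name] for name in member_names])


def default_scheme() -> QidScheme:
    """The 11-variable census scheme (8 distinct qids after ethnicity grouping).

    Category counts follow the published long-form census coding: 5-year age
    bands (24), gender (2), language spoken most often at home (4), ethnic
    origin (26), aboriginal identity (8), religious denomination (3), total
    years of schooling (9), legal marital status (5), total income in $15K
    bands (22), visible minority status (4), activity difficulties (4).
    """
    eth = dict(ethnicity_group_member=True)
    return QidScheme(
        variables=(
            QuasiIdentifier("gender", 2, "high_utility"),
            QuasiIdentifier("age", 24, "high_utility"),
            QuasiIdentifier("language", 4, "sensitive", **eth),
            QuasiIdentifier("ethnic_origin", 26, "sensitive", **eth),
            QuasiIdentifier("religion", 3, "sensitive", **eth),
            QuasiIdentifier("visible_minority", 4, "sensitive", **eth),
            QuasiIdentifier("schooling", 9, "sensitive"),
            QuasiIdentifier("marital_status", 5, "sensitive"),
            QuasiIdentifier("income", 22, "sensitive"),
            QuasiIdentifier("aboriginal_identity", 8, "sensitive"),
            QuasiIdentifier("activity_difficulties", 4, "sensitive"),
        ),
        ethnicity_variants=("language", "ethnic_origin", "religion", "visible_minority"),
    )


def max_combs(model_members: Sequence[QuasiIdentifier]) -> int:
    """Maximum number of equivalence classes of a quasi-identifier model.

    This is the product of the members' response-category counts; e.g. age
    (24) x marital status (5) x schooling (9) x religion (3) = 3,240.
    """
    members = list(model_members)
    if not members:
        raise SchemeError("a quasi-identifier model needs at least one member")
    return math.prod(int(v.n_categories) for v in members)


@dataclass(frozen=True, order=True)
class QidModel:
    """A concrete quasi-identifier model: 2-5 named variables and its MaxCombs.

    Ordering is by model size then lexicographic member names, which gives the
    deterministic enumeration order used throughout the package.
    """

    size: int = field(init=False)
    members: tuple[str, ...]
    max_combs: int = field(compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))
        object.__setattr__(self, "size", len(self.members))
        if len(set(self.members)) != len(self.members):
            raise SchemeError(f"duplicate members in model: {self.members}")
        if self.max_combs < 1:
            raise SchemeError("max_combs must be positive")

    @property
    def model_id(self) -> str:
        return "+".join(self.members)


def enumerate_models(
    scheme: QidScheme,
    *,
    min_size: int = 2,
    max_size: int = 5,
) -> list[QidModel]:
    """Enumerate all quasi-identifier models of a scheme.

    A model is a subset of ``min_size``-``max_size`` distinct qids containing
    at least one high-utility variable (age or gender in the default scheme);
    any remaining members are sensitive.  The scheme's ethnicity variants are
    treated as one generic ethnicity qid during subset enumeration, and each
    subset containing it is expanded into one concrete model per variant; the
    generic placeholder itself is never emitted.

    On the default scheme this yields 358 models: 90 containing both age and
    gender, 134 with age only and 134 with gender only.

    Returns a deduplicated list sorted by model size then member names.
    """
    if not (1 <= min_size <= max_size):
        raise ConfigurationError(
            f"invalid model size range [{min_size}, {max_size}]"
        )
    high = list(scheme.high_utility_names())
    if not high:
        raise ConfigurationError("scheme declares no high-utility quasi-identifier")
    variants = list(scheme.ethnicity_variants)
    distinct = high + [
        v.name
        for v in scheme.variables
        if v.utility_class == "sensitive" and v.name not in variants
    ]
    if variants:
        distinct.append(ETHNICITY_PLACEHOLDER)

    seen: set[frozenset[str]] = set()
    for size in range(min_size, max_size + 1):
        for combo in combinations(distinct, size):
            if not any(m in high for m in combo):
                continue
            if ETHNICITY_PLACEHOLDER in combo:
                base = [m for m in combo if m != ETHNICITY_PLACEHOLDER]
                for variant in variants:
                    seen.add(frozenset(base + [variant]))
            else:
                seen.add(frozenset(combo))

    models = [
        QidModel(members=tuple(sorted(m)), max_combs=scheme.max_combs(m)) for m in seen
    ]
    return sorted(models)
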