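"""End-to-end suppression reports: flag small areas and count affected records.

Given a user dataset (one row per person with an area code), an
area-population lookup and a decision rule — a fitted/published logistic
threshold model, or the stringent zero-uniqueness rule — the report lists
each area's flag and the fraction of records that would be suppressed if
every flagged area were withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import MissingPopulationError, ParameterError
from .risk_model import LogitRiskModel
from .schemes import QidModel, QidScheme
from .uniqueness import (
    RecordTable,
    equivalence_classes,
    zayatz_population_uniqueness,
)

__all__ = ["ZERO_RULE", "SuppressionReport", "suppression_report"]

#: Sentinel selecting the 0%-threshold rule: flag any area whose estimated
#: population uniqueness is greater than zero.
ZERO_RULE = "zero"


@dataclass
class SuppressionReport:
    threshold_label: str
    rule: str
    areas: pd.DataFrame  # columns: area, n_records, probability, flagged
    records_total: int
    records_suppressed: int
    max_combs: int

    @property
    def percent_suppressed(self) -> float:
        return 100.0 * self.records_suppressed / self.records_total

    def to_dict(self) -> dict:
        return {
            "threshold_label": self.threshold_label,
            "rule": self.rule,
            "max_combs": int(self.max_combs),
            "records_total": int(self.records_total),
            "records_suppressed": int(self.records_suppressed),
            "percent_suppressed": self.percent_suppressed,
            "areas": [
                {
                    "area": str(r.area),
                    "n_records": int(r.n_records),
                    "probability": float(r.probability),
                    "flagged": bool(r.flagged),
                }
                for r in self.areas.itertuples()
            ],
        }


def suppression_report(
    records: RecordTable,
    pop_table: pd.Series,
    model: LogitRiskModel | str,
    scheme: QidScheme,
    members: Sequence[str],
    *,
    cutoff: float = 0.5,
    subsampling: str = "binomial",
) -> SuppressionReport:
    """Flag every area in ``records`` and tally suppressed record counts.

    ``model`` is a :class:`LogitRiskModel` (5% or 20% threshold) or the
    string ``"zero"`` for the 0%-uniqueness rule, under which an area is
    flagged when its Zayatz-estimated population uniqueness on ``members``
    exceeds zero.  For a logistic model the area's predicted probability
    uses its population count and the MaxCombs of ``members``; for the zero
    rule the reported ``probability`` column carries the uniqueness
    estimate itself.
    """
    counts = records.df.groupby(records.area_col).size()
    missing = sorted(set(counts.index) - set(pop_table.index))
    if missing:
        raise MissingPopulationError(
            f"areas without a population-table entry: {missing[:20]}"
        )
    max_combs = scheme.max_combs(members)
    model_obj: QidModel = QidModel(members=tuple(members), max_combs=max_combs)

    rows = []
    if isinstance(model, str):
        if model != ZERO_RULE:
            raise ParameterError(f"unknown rule {model!r}; use a model or 'zero'")
        label, rule = "0%", "zero_uniqueness"
        for area, n_rec in counts.items():
            spectrum = equivalence_classes(records, model_obj, area)
            est = zayatz_population_uniqueness(
                spectrum,
                records.sampling_fraction,
                int(pop_table.loc[area]),
                subsampling=subsampling,
            )
            rows.append((area, int(n_rec), est, est > 0.0))
    else:
        label, rule = model.threshold_label, "logit_model"
        for area, n_rec in counts.items():
            pi = float(
                model.predict_probability(int(pop_table.loc[area]), max_combs)
            )
            rows.append((area, int(n_rec), pi, pi > cutoff))

    areas = pd.DataFrame(rows, columns=["area", "n_records", "probability", "flagged"])
    suppressed = int(areas.loc[areas.flagged, "n_records"].sum())
    return SuppressionReport(
        threshold_label=label,
        rule=rule,
        areas=areas,
        records_total=int(counts.sum()),
        records_suppressed=suppressed,
        max_combs=max_combs,
    )
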