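"""Per-species return-on-investment scoring.

For a species judged (highly probably or definitely) to harbor
undescribed species, the ROI statistic is

    ROI = (c1 + c2 + c3 + c4) * tax / (r1 + r2 + r3 + r4)

where c1..c4 are the binary conservation-benefit flags, r1..r4 the
binary outstanding research steps (the categorical "cost"), and *tax*
the confidence weight that revision is needed (0 / 0.2 / 0.8 / 1.0 for
none / probably-not / highly-probable / definite).  ROI at or above the
priority threshold (default 1.0) marks a species whose predicted
conservation payoff is high relative to the research still required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CohortError, ZeroCostError
from .types import RevisionOutcome, SpeciesAssessment, TaxonConfidence

DEFAULT_WEIGHTS: dict[TaxonConfidence, float] = {
    TaxonConfidence.NONE: 0.0,
    TaxonConfidence.PROBABLY_NOT: 0.2,
    TaxonConfidence.HIGHLY_PROBABLE: 0.8,
    TaxonConfidence.DEFINITE: 1.0,
}


@dataclass(frozen=True)
class TaxWeightTable:
    """Confidence -> tax weight; must be monotone non-decreasing in [0, 1]."""

    weights: Mapping[TaxonConfidence, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        levels = list(TaxonConfidence)
        missing = [c for c in levels if c not in self.weights]
        if missing:
            raise ValueError(f"weights missing for {missing}")
        vals = [float(self.weights[c]) for c in levels]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("tax weights must lie in [0, 1]")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("tax weights must be monotone non-decreasing")

    def weight(self, confidence: TaxonConfidence) -> float:
        return float(self.weights[confidence])

    def scaled(self, k: float) -> "TaxWeightTable":
        return TaxWeightTable({c: k * w for c, w in self.weights.items()})


@dataclass(frozen=True)
class RoiScore:
    species_id: str
    benefit_sum: int
    cost_sum: int
    tax_weight: float
    roi: float
    is_priority: bool
    family: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.benefit_sum <= 4):
            raise ValueError("benefit_sum out of [0, 4]")
        if not (1 <= self.cost_sum <= 4):
            raise ValueError("cost_sum out of [1, 4]")
        if not (0.0 < self.tax_weight <= 1.0):
            raise ValueError("tax_weight out of (0, 1]")


def roi_score(
    assessment: SpeciesAssessment,
    weights: Optional[TaxWeightTable] = None,
    threshold: float = 1.0,
) -> RoiScore:
    """Score one assessment; it must carry a positive tax weight and at
    least one outstanding research step.

    Raises ZeroCostError when all four research steps are complete
    (a pending revision always has at least analysis/manuscript work
    outstanding) and CohortError when the tax weight is zero.
    """
    weights = weights or TaxWeightTable()
    tax = weights.weight(assessment.confidence)
    if tax <= 0.0:
        raise CohortError(
            f"{assessment.species_id}: tax weight is 0 "
            f"(confidence {assessment.confidence.name.lower()})"
        )
    cost = assessment.research.cost_sum
    if cost == 0:
        raise ZeroCostError(
            f"{assessment.species_id}: no outstanding research steps"
        )
    benefit = assessment.conservation.benefit_sum
    value = benefit * tax / cost
    return RoiScore(
        species_id=assessment.species_id,
        benefit_sum=benefit,
        cost_sum=cost,
        tax_weight=tax,
        roi=value,
        is_priority=value >= threshold,
        family=assessment.family,
    )


def score_cohort(
    assessments: Sequence[SpeciesAssessment],
    weights: Optional[TaxWeightTable] = None,
    threshold: float = 1.0,
    permissive: bool = False,
) -> tuple[list[RoiScore], int]:
    """Score a cohort, sorted by descending ROI (ties by species_id).

    The default cohort rule requires outcome = increase; `permissive`
    relaxes that to any species with a positive tax weight.  Returns the
    sorted scores and the number of priority species.
    """
    weights = weights or TaxWeightTable()
    scores: list[RoiScore] = []
    for a in assessments:
        if not permissive and a.outcome is not RevisionOutcome.INCREASE:
            raise CohortError(
                f"{a.species_id}: outcome {a.outcome.value!r} is outside the "
                "ROI cohort (expected 'increase'; use permissive=True to relax)"
            )
        try:
            scores.append(roi_score(a, weights=weights, threshold=threshold))
        except (CohortError, ZeroCostError) as exc:
            raise type(exc)(str(exc)) from None
    scores.sort(key=lambda s: (-s.roi, s.species_id))
    return scores, sum(s.is_priority for s in scores)


def scores_to_records(scores: Iterable[RoiScore]) -> list[dict]:
    return [
        {
            "species_id": s.species_id,
            "family": s.family,
            "benefit_sum": s.benefit_sum,
            "cost_sum": s.cost_sum,
            "tax_weight": s.tax_weight,
            "roi": s.roi,
            "is_priority": s.is_priority,
        }
        for s in scores
    ]
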