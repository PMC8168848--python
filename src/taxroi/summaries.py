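"""Headline aggregate statistics from a resolved assessment table.

Four products: a census of taxonomic uncertainty (how many species were
assessed, how many probably/definitely need revision, and the predicted
outcome mix); a per-family summary with revision-rate and assessment-
coverage flags; a research-needs profile over the sixteen combinations
of outstanding steps, including the "backlog" of species whose field and
genetic work is done but whose descriptions remain unwritten; and a
conservation summary (highly localized candidates, and candidates of
conservation concern).

Counts are stored exactly; percentages are recomputed from counts and
rounded half-up to one decimal only at report rendering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .errors import ValidationError, ZeroCostError
from .types import (
    HigherGroup,
    RevisionOutcome,
    SpeciesAssessment,
    TaxonConfidence,
)

Combo = tuple[int, int, int, int]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention for reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def _needs_revision(r: SpeciesAssessment) -> bool:
    return r.confidence >= TaxonConfidence.HIGHLY_PROBABLE


@dataclass(frozen=True)
class CensusSummary:
    """Counts of assessed species by revision need and predicted outcome."""

    n_total_species: int
    n_assessed: int
    n_revision: int
    n_increase: int
    n_decrease: int
    n_complex: int

    @property
    def pct_assessed(self) -> float:
        return _pct(self.n_assessed, self.n_total_species)

    @property
    def pct_revision_of_assessed(self) -> float:
        return _pct(self.n_revision, self.n_assessed)

    @property
    def pct_increase_of_assessed(self) -> float:
        return _pct(self.n_increase, self.n_assessed)

    @property
    def pct_increase_incl_complex(self) -> float:
        return _pct(self.n_increase + self.n_complex, self.n_assessed)

    def as_dict(self) -> dict:
        return {
            "n_total_species": self.n_total_species,
            "n_assessed": self.n_assessed,
            "pct_assessed": round_half_up(self.pct_assessed),
            "n_revision": self.n_revision,
            "pct_revision_of_assessed": round_half_up(self.pct_revision_of_assessed),
            "n_increase": self.n_increase,
            "n_decrease": self.n_decrease,
            "n_complex": self.n_complex,
            "pct_increase_of_assessed": round_half_up(self.pct_increase_of_assessed),
            "pct_increase_incl_complex": round_half_up(self.pct_increase_incl_complex),
        }


def census(records: Sequence[SpeciesAssessment], n_total_species: int) -> CensusSummary:
    """Census of a resolved table against the full species pool size."""
    if n_total_species < len(records):
        raise ValidationError(
            f"n_total_species ({n_total_species}) is smaller than the number "
            f"of assessed records ({len(records)})"
        )
    revision = [r for r in records if _needs_revision(r)]
    return CensusSummary(
        n_total_species=n_total_species,
        n_assessed=len(records),
        n_revision=len(revision),
        n_increase=sum(r.outcome is RevisionOutcome.INCREASE for r in revision),
        n_decrease=sum(r.outcome is RevisionOutcome.DECREASE for r in revision),
        n_complex=sum(r.outcome is RevisionOutcome.SPECIES_COMPLEX for r in revision),
    )


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n_species: int
    n_assessed: int
    n_increase: int
    high_revision_threshold: float = 30.0
    coverage_threshold: float = 75.0

    @property
    def pct_increase(self) -> float:
        return _pct(self.n_increase, self.n_assessed)

    @property
    def flag_high_revision(self) -> bool:
        return self.n_assessed > 0 and self.pct_increase >= self.high_revision_threshold

    @property
    def flag_low_coverage(self) -> bool:
        return _pct(self.n_assessed, self.n_species) < self.coverage_threshold

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "n_species": self.n_species,
            "n_assessed": self.n_assessed,
            "n_increase": self.n_increase,
            "pct_increase": round_half_up(self.pct_increase),
            "flag_high_revision": self.flag_high_revision,
            "flag_low_coverage": self.flag_low_coverage,
        }


def family_summary(
    records: Sequence[SpeciesAssessment],
    family_totals: Optional[Mapping[str, int]] = None,
) -> list[FamilySummary]:
    """Per-family assessment coverage and predicted-increase rates.

    `family_totals` gives the full species count per family (for the
    coverage flag); without it, each family's pool is taken to be the
    species assessed, i.e. full coverage.
    """
    for r in records:
        if not r.family:
            raise ValidationError(f"{r.species_id}: empty family")
    fams = sorted({r.family for r in records})
    out = []
    for fam in fams:
        members = [r for r in records if r.family == fam]
        n_inc = sum(
            _needs_revision(r) and r.outcome is RevisionOutcome.INCREASE
            for r in members
        )
        n_total = (family_totals or {}).get(fam, len(members))
        out.append(
            FamilySummary(
                family=fam, n_species=n_total, n_assessed=len(members),
                n_increase=n_inc,
            )
        )
    return out


@dataclass(frozen=True)
class ResearchProfile:
    """Outstanding-research composition of the increase cohort.

    combination_counts maps each (fieldwork, genetics, morphology,
    analysis) pattern to its count, overall and per higher group.
    Backlog species have fieldwork and genetics complete (both 0) but at
    least one of morphology/analysis outstanding.
    """

    cohort_size: int
    combination_counts: Mapping[Combo, int]
    by_group: Mapping[HigherGroup, Mapping[Combo, int]]
    backlog_count: int

    @property
    def backlog_pct(self) -> float:
        return _pct(self.backlog_count, self.cohort_size)

    def group_size(self, group: HigherGroup) -> int:
        return sum(self.by_group.get(group, {}).values())

    def analysis_only_count(self, group: Optional[HigherGroup] = None) -> int:
        """Species needing only analysis and manuscript preparation."""
        src = self.combination_counts if group is None else self.by_group.get(group, {})
        return src.get((0, 0, 0, 1), 0)

    def as_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "backlog_count": self.backlog_count,
            "backlog_pct": round_half_up(self.backlog_pct),
            "combinations": {
                "".join(map(str, combo)): n
                for combo, n in sorted(self.combination_counts.items())
            },
            "by_group": {
                g.value: {"".join(map(str, c)): n for c, n in sorted(cc.items())}
                for g, cc in self.by_group.items()
            },
        }


def research_profile(records: Sequence[SpeciesAssessment]) -> ResearchProfile:
    """Profile the increase cohort's outstanding research steps."""
    combos: dict[Combo, int] = {}
    by_group: dict[HigherGroup, dict[Combo, int]] = {}
    backlog = 0
    for r in records:
        if r.outcome is not RevisionOutcome.INCREASE:
            raise ValidationError(
                f"{r.species_id}: research profile expects the increase cohort "
                f"(got outcome {r.outcome.value!r})"
            )
        combo = r.research.as_tuple()
        if sum(combo) == 0:
            raise ZeroCostError(
                f"{r.species_id}: all research steps complete yet revision "
                "still pending — inconsistent record"
            )
        combos[combo] = combos.get(combo, 0) + 1
        by_group.setdefault(r.higher_group, {})
        by_group[r.higher_group][combo] = by_group[r.higher_group].get(combo, 0) + 1
        if combo[0] == 0 and combo[1] == 0 and (combo[2] == 1 or combo[3] == 1):
            backlog += 1
    return ResearchProfile(
        cohort_size=len(records),
        combination_counts=combos,
        by_group=by_group,
        backlog_count=backlog,
    )


ALL_COMBOS: tuple[Combo, ...] = tuple(itertools.product((0, 1), repeat=4))


@dataclass(frozen=True)
class ConservationSummary:
    """Conservation flags over the increase cohort.

    "Concern" counts species flagged for a threatening process or a high
    probability of threatened status (rule="either", the default) or for
    the latter alone (rule="high_threat_only").
    """

    cohort_size: int
    n_highly_localized: int
    n_concern: int
    concern_rule: str = "either"

    @property
    def pct_highly_localized(self) -> float:
        return _pct(self.n_highly_localized, self.cohort_size)

    @property
    def pct_concern(self) -> float:
        return _pct(self.n_concern, self.cohort_size)

    def as_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "n_highly_localized": self.n_highly_localized,
            "pct_highly_localized": round_half_up(self.pct_highly_localized),
            "n_concern": self.n_concern,
            "pct_concern": round_half_up(self.pct_concern),
            "concern_rule": self.concern_rule,
        }


def conservation_summary(
    records: Sequence[SpeciesAssessment], concern_rule: str = "either"
) -> ConservationSummary:
    if not records:
        raise ValidationError("empty cohort: conservation percentages undefined")
    if concern_rule not in ("either", "high_threat_only"):
        raise ValueError(f"unknown concern_rule {concern_rule!r}")
    n_loc = sum(r.conservation.highly_localized for r in records)
    if concern_rule == "either":
        n_con = sum(
            1
            for r in records
            if r.conservation.threatening_process
            or r.conservation.high_threat_probability
        )
    else:
        n_con = sum(r.conservation.high_threat_probability for r in records)
    return ConservationSummary(
        cohort_size=len(records),
        n_highly_localized=n_loc,
        n_concern=n_con,
        concern_rule=concern_rule,
    )
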