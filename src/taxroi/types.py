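"""Core domain types for expert-elicitation taxonomic assessments.

An assessment records, for one currently recognized species, an expert
panel's judgment of (a) how confident they are that the species needs
taxonomic revision, (b) what the revision would do to species counts
(increase, decrease, or an unresolvable species complex), (c) which of
four research steps remain before the revision can be completed, and
(d) four binary conservation-benefit flags for the candidate species
expected to result from the revision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class TaxonConfidence(enum.IntEnum):
    """Expert confidence that a species needs taxonomic revision.

    Ordered: NONE < PROBABLY_NOT < HIGHLY_PROBABLE < DEFINITE.  The two
    highest categories form the "revision needed" cohort used in all
    downstream analyses; each category maps to a numeric *tax* weight
    (see :class:`taxroi.roi.TaxWeightTable`).
    """

    NONE = 0
    PROBABLY_NOT = 1
    HIGHLY_PROBABLE = 2
    DEFINITE = 3


class RevisionOutcome(enum.Enum):
    """Predicted effect of a completed revision on species number.

    Mutually exclusive. SPECIES_COMPLEX marks groups too tangled for a
    net increase/decrease prediction; NONE means no outcome recorded.
    """

    INCREASE = "increase"
    DECREASE = "decrease"
    SPECIES_COMPLEX = "species_complex"
    NONE = "none"


class HigherGroup(enum.Enum):
    LIZARD = "lizard"
    SNAKE = "snake"
    OTHER = "other"


class ConflictCategory(enum.IntEnum):
    """Categories of multi-assessor disagreement on revision need.

    MORPH_VS_GENETIC: morphology suggests candidate species, unpublished
    genetic data says within-species variation (resolved: no revision).
    ISOLATED_NO_GENETIC: morphology suggests an isolated short-range
    candidate but no genetic data exist (resolved: highly probable).
    ALREADY_DESCRIBED: the candidate was recently described and one
    assessor was unaware (resolved: no revision).
    """

    MORPH_VS_GENETIC = 1
    ISOLATED_NO_GENETIC = 2
    ALREADY_DESCRIBED = 3


def _check_binary(name: str, value: int) -> int:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class ResearchNeeds:
    """Outstanding research steps, binary-coded (1 = still needed)."""

    fieldwork: int = 0
    genetics: int = 0
    morphology: int = 0
    analysis: int = 0

    def __post_init__(self) -> None:
        for name in ("fieldwork", "genetics", "morphology", "analysis"):
            _check_binary(name, getattr(self, name))

    @property
    def cost_sum(self) -> int:
        return self.fieldwork + self.genetics + self.morphology + self.analysis

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.fieldwork, self.genetics, self.morphology, self.analysis)


@dataclass(frozen=True)
class ConservationFlags:
    """Predicted conservation benefits of completing the revision.

    enables_assessment: describing the candidate species makes formal
    conservation (Red List) assessment possible.
    highly_localized: a candidate species is expected to have an extent
    of occurrence below 20,000 km^2 (the Red List Vulnerable range
    threshold).
    threatening_process: candidate species subject to a species-level
    threatening process.
    high_threat_probability: high probability a candidate species would
    be assessed Vulnerable/Endangered/Critically Endangered.

    Unassessed flags default to 0 (the conservative convention).
    """

    enables_assessment: int = 0
    highly_localized: int = 0
    threatening_process: int = 0
    high_threat_probability: int = 0

    def __post_init__(self) -> None:
        for name in (
            "enables_assessment",
            "highly_localized",
            "threatening_process",
            "high_threat_probability",
        ):
            _check_binary(name, getattr(self, name))

    @property
    def benefit_sum(self) -> int:
        return (
            self.enables_assessment
            + self.highly_localized
            + self.threatening_process
            + self.high_threat_probability
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.enables_assessment,
            self.highly_localized,
            self.threatening_process,
            self.high_threat_probability,
        )


def normalize_species_id(raw: str) -> str:
    """Collapse internal whitespace and strip; identity is case-insensitive
    but the stored form keeps the original casing."""
    return " ".join(str(raw).split())


@dataclass(frozen=True)
class SpeciesAssessment:
    """One expert judgment of one species (raw, or resolved per species)."""

    species_id: str
    confidence: TaxonConfidence
    outcome: RevisionOutcome = RevisionOutcome.NONE
    research: ResearchNeeds = field(default_factory=ResearchNeeds)
    conservation: ConservationFlags = field(default_factory=ConservationFlags)
    family: str = ""
    higher_group: HigherGroup = HigherGroup.OTHER
    assessor_id: Optional[str] = None
    notes_taxonomy: str = ""
    notes_research: str = ""
    notes_conservation: str = ""

    def __post_init__(self) -> None:
        sid = normalize_species_id(self.species_id)
        if not sid:
            raise ValueError("species_id must be non-empty")
        object.__setattr__(self, "species_id", sid)

    @property
    def key(self) -> str:
        """Case-insensitive identity key."""
        return self.species_id.casefold()

    @property
    def needs_revision(self) -> bool:
        return self.confidence >= TaxonConfidence.HIGHLY_PROBABLE

    def without_assessor(self) -> "SpeciesAssessment":
        return replace(self, assessor_id=None)


@dataclass(frozen=True)
class AssessmentConflict:
    """A multi-assessor disagreement and its deterministic resolution."""

    species_id: str
    raw_records: tuple[SpeciesAssessment, ...]
    conflict_category: ConflictCategory
    resolution: SpeciesAssessment

    def __post_init__(self) -> None:
        if len(self.raw_records) < 2:
            raise ValueError("a conflict needs at least two raw records")
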