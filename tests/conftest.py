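import pytest

from taxroi.types import (
    ConservationFlags,
    HigherGroup,
    ResearchNeeds,
    RevisionOutcome,
    SpeciesAssessment,
    TaxonConfidence,
)


def make_assessment(
    species_id="Ctenotus alpha",
    confidence=TaxonConfidence.HIGHLY_PROBABLE,
    outcome=RevisionOutcome.INCREASE,
    research=(0, 0, 0, 1),
    conservation=(1, 0, 0, 0),
    family="Scincidae",
    higher_group=HigherGroup.LIZARD,
    assessor_id=None,
):
    return SpeciesAssessment(
        species_id=species_id,
        confidence=confidence,
        outcome=outcome,
        research=ResearchNeeds(*research),
        conservation=ConservationFlags(*conservation),
        family=family,
        higher_group=higher_group,
        assessor_id=assessor_id,
    )


@pytest.fixture
def assessment_factory():
    return make_assessment
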