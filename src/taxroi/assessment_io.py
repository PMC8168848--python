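"""Read, validate, canonicalize and de-conflict expert assessment tables.

The canonical table has one row per species x assessor with the columns

    species_id, family, higher_group, assessor_id, confidence, outcome,
    r_fieldwork, r_genetics, r_morphology, r_analysis,
    c_enables_assessment, c_highly_localized, c_threatening_process,
    c_high_threat_probability,
    notes_taxonomy, notes_research, notes_conservation

Source spreadsheets rarely use these exact headers, so every reader takes
an alias map (canonical name -> source header).  Binary cells are coerced
to {0, 1}; blank research/conservation cells fall back to the conservative
default 0 (with a logged warning), while a blank confidence cell is a hard
error.  `c_enables_assessment` is special: when blank or absent it is
derived as 1 for species whose predicted outcome is an increase in species
number (describing the candidate species is what makes its conservation
assessment possible) and 0 otherwise; an explicit cell value always wins.

Multi-assessor disagreements on revision need are resolved with the
three-category rule: morphology-versus-genetics conflicts and
already-described species are coded as not needing revision; isolated
candidates lacking genetic data are coded as highly probable.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, UnresolvedConflictError, ValidationError
from .types import (
    AssessmentConflict,
    ConflictCategory,
    ConservationFlags,
    HigherGroup,
    ResearchNeeds,
    RevisionOutcome,
    SpeciesAssessment,
    TaxonConfidence,
)

logger = logging.getLogger(__name__)

RESEARCH_COLUMNS = ("r_fieldwork", "r_genetics", "r_morphology", "r_analysis")
CONSERVATION_COLUMNS = (
    "c_enables_assessment",
    "c_highly_localized",
    "c_threatening_process",
    "c_high_threat_probability",
)
REQUIRED_COLUMNS = ("species_id", "confidence", "outcome") + RESEARCH_COLUMNS
OPTIONAL_COLUMNS = (
    ("family", "higher_group", "assessor_id")
    + CONSERVATION_COLUMNS
    + ("notes_taxonomy", "notes_research", "notes_conservation")
)
CANONICAL_COLUMNS = REQUIRED_COLUMNS[:3] + (
    "family",
    "higher_group",
    "assessor_id",
) + RESEARCH_COLUMNS + CONSERVATION_COLUMNS + (
    "notes_taxonomy",
    "notes_research",
    "notes_conservation",
)

# Built-in header aliases (all compared case/space-insensitively).
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "species_id": ("species_id", "species", "species name", "taxon", "scientific name"),
    "family": ("family",),
    "higher_group": ("higher_group", "group", "suborder"),
    "assessor_id": ("assessor_id", "assessor", "research group"),
    "confidence": ("confidence", "taxonomic confidence", "revision confidence", "tax confidence"),
    "outcome": ("outcome", "revision outcome", "predicted outcome", "taxonomic outcome"),
    "r_fieldwork": ("r_fieldwork", "r1", "fieldwork", "fieldwork and additional sampling"),
    "r_genetics": ("r_genetics", "r2", "genetics", "genetics/genomics"),
    "r_morphology": ("r_morphology", "r3", "morphology", "morphological data"),
    "r_analysis": ("r_analysis", "r4", "analysis", "analysis and manuscript preparation"),
    "c_enables_assessment": ("c_enables_assessment", "c1", "enables assessment"),
    "c_highly_localized": ("c_highly_localized", "c2", "highly localized", "highly localised"),
    "c_threatening_process": ("c_threatening_process", "c3", "threatening process"),
    "c_high_threat_probability": (
        "c_high_threat_probability",
        "c4",
        "high threat probability",
        "probability threatened",
    ),
    "notes_taxonomy": ("notes_taxonomy", "taxonomy notes"),
    "notes_research": ("notes_research", "research notes"),
    "notes_conservation": ("notes_conservation", "conservation notes"),
}

_CONFIDENCE_SYNONYMS = {
    "none": TaxonConfidence.NONE,
    "no": TaxonConfidence.NONE,
    "no revision": TaxonConfidence.NONE,
    "no_revision": TaxonConfidence.NONE,
    "0": TaxonConfidence.NONE,
    "0.0": TaxonConfidence.NONE,
    "probably not": TaxonConfidence.PROBABLY_NOT,
    "probably_not": TaxonConfidence.PROBABLY_NOT,
    "0.2": TaxonConfidence.PROBABLY_NOT,
    "highly probable": TaxonConfidence.HIGHLY_PROBABLE,
    "highly_probable": TaxonConfidence.HIGHLY_PROBABLE,
    "high probability": TaxonConfidence.HIGHLY_PROBABLE,
    "0.8": TaxonConfidence.HIGHLY_PROBABLE,
    "definite": TaxonConfidence.DEFINITE,
    "definitely": TaxonConfidence.DEFINITE,
    "1": TaxonConfidence.DEFINITE,
    "1.0": TaxonConfidence.DEFINITE,
}

_OUTCOME_SYNONYMS = {
    "increase": RevisionOutcome.INCREASE,
    "decrease": RevisionOutcome.DECREASE,
    "synonymy": RevisionOutcome.DECREASE,
    "species complex": RevisionOutcome.SPECIES_COMPLEX,
    "species_complex": RevisionOutcome.SPECIES_COMPLEX,
    "complex": RevisionOutcome.SPECIES_COMPLEX,
    "none": RevisionOutcome.NONE,
    "": RevisionOutcome.NONE,
}

_GROUP_SYNONYMS = {
    "lizard": HigherGroup.LIZARD,
    "lizards": HigherGroup.LIZARD,
    "snake": HigherGroup.SNAKE,
    "snakes": HigherGroup.SNAKE,
    "": HigherGroup.OTHER,
    "other": HigherGroup.OTHER,
}


def _norm_header(h: str) -> str:
    return " ".join(str(h).strip().lower().replace("_", " ").split())


def _resolve_columns(
    headers: Sequence[str], column_map: Optional[Mapping[str, str]]
) -> dict[str, str]:
    """Map canonical column names to actual source headers."""
    by_norm = {_norm_header(h): h for h in headers}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon in CANONICAL_COLUMNS:
        if canon in column_map:
            src = column_map[canon]
            if src not in headers and _norm_header(src) not in by_norm:
                raise SchemaError(
                    f"column_map maps {canon!r} to {src!r}, absent from the file"
                )
            resolved[canon] = src if src in headers else by_norm[_norm_header(src)]
            continue
        for alias in DEFAULT_ALIASES[canon]:
            if _norm_header(alias) in by_norm:
                resolved[canon] = by_norm[_norm_header(alias)]
                break
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise SchemaError(f"required column(s) not resolvable: {', '.join(missing)}")
    return resolved


def _cell(row: pd.Series, colmap: dict[str, str], canon: str) -> str:
    if canon not in colmap:
        return ""
    val = row[colmap[canon]]
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return ""
    return str(val).strip()


def _coerce_binary(raw: str, *, column: str, row: int, blank_default: int | None) -> int:
    if raw == "":
        if blank_default is None:
            raise ValidationError(f"blank value in binary column {column!r}", row=row)
        logger.warning("row %d: blank %s coerced to %d", row, column, blank_default)
        return blank_default
    try:
        num = float(raw)
    except ValueError:
        raise ValidationError(
            f"non-binary value {raw!r} in column {column!r}", row=row
        ) from None
    if num not in (0.0, 1.0):
        raise ValidationError(f"non-binary value {raw!r} in column {column!r}", row=row)
    return int(num)


def _parse_confidence(raw: str, row: int) -> TaxonConfidence:
    if raw == "":
        raise ValidationError("blank confidence (no conservative default exists)", row=row)
    key = " ".join(raw.lower().split())
    if key not in _CONFIDENCE_SYNONYMS:
        raise ValidationError(f"unrecognized confidence value {raw!r}", row=row)
    return _CONFIDENCE_SYNONYMS[key]


def _parse_outcome(raw: str, row: int) -> RevisionOutcome:
    key = " ".join(raw.lower().split())
    if key not in _OUTCOME_SYNONYMS:
        raise ValidationError(f"unrecognized outcome value {raw!r}", row=row)
    return _OUTCOME_SYNONYMS[key]


def _load_frame(source: str | Path, sheet: int | str) -> pd.DataFrame:
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, sheet_name=sheet, dtype=str, keep_default_na=False)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_assessments(
    source: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    sheet: int | str = 0,
) -> list[SpeciesAssessment]:
    """Parse a CSV/XLSX assessment table into raw per-row records.

    Raises SchemaError when a required column cannot be resolved and
    ValidationError (with the offending 0-based data row index) for
    out-of-domain cell values.
    """
    frame = _load_frame(source, sheet)
    colmap = _resolve_columns(list(frame.columns), column_map)
    records: list[SpeciesAssessment] = []
    for idx, row in frame.iterrows():
        i = int(idx)
        sid = _cell(row, colmap, "species_id")
        if not " ".join(sid.split()):
            raise ValidationError("blank species_id", row=i)
        confidence = _parse_confidence(_cell(row, colmap, "confidence"), i)
        outcome = _parse_outcome(_cell(row, colmap, "outcome"), i)
        research = ResearchNeeds(
            *(
                _coerce_binary(_cell(row, colmap, c), column=c, row=i, blank_default=0)
                for c in RESEARCH_COLUMNS
            )
        )
        cvals = {}
        for c in CONSERVATION_COLUMNS:
            raw = _cell(row, colmap, c)
            if c == "c_enables_assessment" and raw == "":
                # derived default: a described candidate species can be assessed
                cvals[c] = 1 if outcome is RevisionOutcome.INCREASE else 0
            else:
                cvals[c] = _coerce_binary(raw, column=c, row=i, blank_default=0)
        conservation = ConservationFlags(
            enables_assessment=cvals["c_enables_assessment"],
            highly_localized=cvals["c_highly_localized"],
            threatening_process=cvals["c_threatening_process"],
            high_threat_probability=cvals["c_high_threat_probability"],
        )
        group_raw = " ".join(_cell(row, colmap, "higher_group").lower().split())
        higher_group = _GROUP_SYNONYMS.get(group_raw, HigherGroup.OTHER)
        records.append(
            SpeciesAssessment(
                species_id=sid,
                confidence=confidence,
                outcome=outcome,
                research=research,
                conservation=conservation,
                family=_cell(row, colmap, "family"),
                higher_group=higher_group,
                assessor_id=_cell(row, colmap, "assessor_id") or None,
                notes_taxonomy=_cell(row, colmap, "notes_taxonomy"),
                notes_research=_cell(row, colmap, "notes_research"),
                notes_conservation=_cell(row, colmap, "notes_conservation"),
            )
        )
    return records


def records_to_frame(records: Iterable[SpeciesAssessment]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "family": r.family,
                "higher_group": r.higher_group.value,
                "assessor_id": r.assessor_id or "",
                "confidence": r.confidence.name.lower(),
                "outcome": r.outcome.value,
                "r_fieldwork": r.research.fieldwork,
                "r_genetics": r.research.genetics,
                "r_morphology": r.research.morphology,
                "r_analysis": r.research.analysis,
                "c_enables_assessment": r.conservation.enables_assessment,
                "c_highly_localized": r.conservation.highly_localized,
                "c_threatening_process": r.conservation.threatening_process,
                "c_high_threat_probability": r.conservation.high_threat_probability,
                "notes_taxonomy": r.notes_taxonomy,
                "notes_research": r.notes_research,
                "notes_conservation": r.notes_conservation,
            }
        )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_assessments(records: Iterable[SpeciesAssessment], path: str | Path) -> None:
    """Write records as a canonical CSV (round-trips through read_assessments)."""
    records_to_frame(records).to_csv(path, index=False)


def _merge_flags(records: Sequence[SpeciesAssessment]) -> tuple[ResearchNeeds, ConservationFlags]:
    """Field-wise maximum: any assessor flagging a need/benefit keeps it."""
    r = [max(rec.research.as_tuple()[k] for rec in records) for k in range(4)]
    c = [max(rec.conservation.as_tuple()[k] for rec in records) for k in range(4)]
    return ResearchNeeds(*r), ConservationFlags(*c)


def _merge_notes(values: Iterable[str]) -> str:
    seen: "OrderedDict[str, None]" = OrderedDict()
    for v in values:
        if v:
            seen.setdefault(v, None)
    return "; ".join(seen)


def _asserting_revision(group: Sequence[SpeciesAssessment]) -> list[SpeciesAssessment]:
    asserting = [
        r
        for r in group
        if r.needs_revision or r.outcome is not RevisionOutcome.NONE
    ]
    return asserting or list(group)


def _merge_group(group: Sequence[SpeciesAssessment]) -> SpeciesAssessment:
    """Collapse concordant records; flags merged by field-wise maximum."""
    base = group[0]
    research, conservation = _merge_flags(_asserting_revision(group))
    return replace(
        base,
        assessor_id=None,
        research=research,
        conservation=conservation,
        notes_taxonomy=_merge_notes(r.notes_taxonomy for r in group),
        notes_research=_merge_notes(r.notes_research for r in group),
        notes_conservation=_merge_notes(r.notes_conservation for r in group),
    )


def _resolve_discordant(
    group: Sequence[SpeciesAssessment], category: ConflictCategory
) -> SpeciesAssessment:
    asserting = _asserting_revision(group)
    research, conservation = _merge_flags(asserting)
    # the record asserting revision with the highest confidence carries the outcome
    lead = max(asserting, key=lambda r: r.confidence)
    merged = replace(
        _merge_group(group),
        research=research,
        conservation=conservation,
    )
    if category is ConflictCategory.ISOLATED_NO_GENETIC:
        return replace(
            merged, confidence=TaxonConfidence.HIGHLY_PROBABLE, outcome=lead.outcome
        )
    # morphology-vs-genetics and already-described: coded as no revision needed
    return replace(
        merged, confidence=TaxonConfidence.NONE, outcome=RevisionOutcome.NONE
    )


def resolve_conflicts(
    records: Sequence[SpeciesAssessment],
    conflict_labels: Optional[Mapping[str, ConflictCategory]] = None,
) -> tuple[list[SpeciesAssessment], list[AssessmentConflict]]:
    """Collapse multi-assessor records into one resolved record per species.

    Discordant groups (differing confidence or outcome) must appear in
    `conflict_labels` (species_id -> ConflictCategory); otherwise an
    UnresolvedConflictError listing the offending species is raised.
    Idempotent: resolving an already-resolved list returns it unchanged.
    """
    labels = { }
    for k, v in (conflict_labels or {}).items():
        labels[" ".join(str(k).split()).casefold()] = ConflictCategory(v)

    groups: "OrderedDict[str, list[SpeciesAssessment]]" = OrderedDict()
    for rec in records:
        groups.setdefault(rec.key, []).append(rec)

    resolved: list[SpeciesAssessment] = []
    conflicts: list[AssessmentConflict] = []
    unresolved: list[str] = []
    for key, group in groups.items():
        if len(group) == 1:
            resolved.append(group[0].without_assessor())
            continue
        discordant = len({(r.confidence, r.outcome) for r in group}) > 1
        if not discordant:
            resolved.append(_merge_group(group))
            continue
        if key not in labels:
            unresolved.append(group[0].species_id)
            continue
        category = labels[key]
        resolution = _resolve_discordant(group, category)
        resolved.append(resolution)
        conflicts.append(
            AssessmentConflict(
                species_id=group[0].species_id,
                raw_records=tuple(group),
                conflict_category=category,
                resolution=resolution,
            )
        )
    if unresolved:
        raise UnresolvedConflictError(unresolved)
    return resolved, conflicts


def filter_revision_cohort(
    records: Sequence[SpeciesAssessment],
    confidence_floor: TaxonConfidence = TaxonConfidence.HIGHLY_PROBABLE,
    outcome_filter: Optional[Iterable[RevisionOutcome]] = None,
) -> list[SpeciesAssessment]:
    """Retain records at/above the confidence floor with an allowed outcome.

    `outcome_filter=None` keeps every outcome (the uncertainty census);
    pass `{RevisionOutcome.INCREASE}` for the ROI cohort.
    """
    allowed = None if outcome_filter is None else set(outcome_filter)
    return [
        r
        for r in records
        if r.confidence >= confidence_floor
        and (allowed is None or r.outcome in allowed)
    ]


def roi_cohort(records: Sequence[SpeciesAssessment]) -> list[SpeciesAssessment]:
    """The default scoring cohort: highly probable or definite revisions
    predicted to increase species number."""
    return filter_revision_cohort(
        records,
        confidence_floor=TaxonConfidence.HIGHLY_PROBABLE,
        outcome_filter={RevisionOutcome.INCREASE},
    )


def conflicts_to_frame(conflicts: Sequence[AssessmentConflict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": c.species_id,
                "category": int(c.conflict_category),
                "n_records": len(c.raw_records),
                "resolution_confidence": c.resolution.confidence.name.lower(),
            }
            for c in conflicts
        ],
        columns=["species_id", "category", "n_records", "resolution_confidence"],
    )
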