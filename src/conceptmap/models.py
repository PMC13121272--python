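"""Core domain types for concept mapping.

A *source concept* is a hospital-local name for a lab test or medication; a
*target concept* is an entry of a standardized vocabulary (a SNOMED-CT-style
lab reference set, or a VTM-level drug dictionary).  A *mapping record* is
one reviewer decision linking a source to a target (or marking it not
relevant / skipped), with audit fields.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator, Optional

from .normalize import normalize_name

__all__ = [
    "Domain",
    "MappingStatus",
    "SourceConcept",
    "TargetConcept",
    "MappingRecord",
    "Vocabulary",
    "InvariantError",
]


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


class Domain(str, enum.Enum):
    LAB_TEST = "lab_test"
    MEDICATION = "medication"


class MappingStatus(str, enum.Enum):
    MAPPED = "mapped"
    NOT_RELEVANT = "not_relevant"
    SKIPPED = "skipped"


@dataclass(frozen=True)
class SourceConcept:
    """A site-local raw concept name with its occurrence frequency.

    ``normalized_name`` is derived, never supplied: it always equals
    ``normalize_name(raw_name)``.  ``(raw_name, site_id, domain)`` identifies
    a source concept within a corpus.
    """

    raw_name: str
    site_id: str
    domain: Domain
    frequency: int
    normalized_name: str = field(init=False)

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise InvariantError(
                f"frequency must be >= 0, got {self.frequency} for {self.raw_name!r}"
            )
        object.__setattr__(self, "domain", Domain(self.domain))
        object.__setattr__(self, "normalized_name", normalize_name(self.raw_name))

    @property
    def key(self) -> str:
        """Stable identifier string used for store entries and deduplication."""
        return f"{self.site_id}|{self.domain.value}|{self.raw_name}"


@dataclass(frozen=True)
class TargetConcept:
    """A standardized vocabulary entry."""

    concept_id: str
    name: str
    vocabulary_id: str
    normalized_name: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "normalized_name", normalize_name(self.name))


@dataclass(frozen=True)
class MappingRecord:
    """One reviewer decision, with audit fields.

    ``status == MAPPED`` if and only if a target is present; similarity at
    decision time is the cosine score of the chosen suggestion, when the
    decision came from the model's list.
    """

    source: SourceConcept
    status: MappingStatus
    target: Optional[TargetConcept] = None
    similarity_at_decision: Optional[float] = None
    reviewer_id: str = ""
    timestamp: datetime = field(default_factory=lambda: datetime(1970, 1, 1))

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", MappingStatus(self.status))
        if (self.status is MappingStatus.MAPPED) != (self.target is not None):
            raise InvariantError(
                f"status {self.status.value!r} inconsistent with "
                f"target {'present' if self.target else 'absent'} "
                f"for source {self.source.raw_name!r}"
            )
        if self.similarity_at_decision is not None and not (
            -1.0 - 1e-9 <= self.similarity_at_decision <= 1.0 + 1e-9
        ):
            raise InvariantError(
                f"similarity_at_decision outside [-1, 1]: {self.similarity_at_decision}"
            )


class Vocabulary:
    """An ordered collection of target concepts with unique concept ids."""

    def __init__(self, vocabulary_id: str, concepts: Iterable[TargetConcept]):
        self.vocabulary_id = vocabulary_id
        self.concepts: list[TargetConcept] = list(concepts)
        seen: dict[str, TargetConcept] = {}
        dupes = []
        for c in self.concepts:
            if c.concept_id in seen:
                dupes.append(c.concept_id)
            seen[c.concept_id] = c
        if dupes:
            raise InvariantError(
                f"duplicate concept_id(s) in vocabulary {vocabulary_id!r}: "
                + ", ".join(sorted(set(dupes)))
            )
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[TargetConcept]:
        return iter(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def get(self, concept_id: str) -> TargetConcept:
        return self._by_id[concept_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return (
            self.vocabulary_id == other.vocabulary_id
            and self.concepts == other.concepts
        )

    def __repr__(self) -> str:
        return f"Vocabulary({self.vocabulary_id!r}, {len(self)} concepts)"
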