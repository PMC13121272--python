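"""Readers and writers for vocabulary, source-concept and mapping tables.

All tables are plain CSV/TSV with a header row.  The mapping table follows
the Usagi-style layout used by OMOP vocabulary-mapping workflows: one row
per reviewer decision, unmapped statuses leave the target columns empty.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import (
    Domain,
    InvariantError,
    MappingRecord,
    MappingStatus,
    SourceConcept,
    TargetConcept,
    Vocabulary,
)

__all__ = [
    "SchemaError",
    "load_vocabulary",
    "load_source_concepts",
    "export_mappings",
    "read_mappings",
    "MAPPING_COLUMNS",
]


class SchemaError(ValueError):
    """A table is missing required columns or contains invalid values."""


VOCAB_COLUMNS = ("concept_id", "concept_name", "vocabulary_id")
SOURCE_COLUMNS = ("raw_name", "site_id", "domain", "frequency")
MAPPING_COLUMNS = (
    "source_name",
    "source_site",
    "source_frequency",
    "target_concept_id",
    "target_name",
    "match_score",
    "mapping_status",
    "reviewer_id",
    "timestamp",
)


def _read_table(path: str | Path, fmt: str) -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown table format {fmt!r}; expected 'csv' or 'tsv'")
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def load_vocabulary(path: str | Path, fmt: str = "csv") -> Vocabulary:
    """Load a target vocabulary from a CSV/TSV table.

    Requires columns ``concept_id, concept_name, vocabulary_id``; row order
    is preserved and duplicate concept ids raise an error listing the
    offenders.
    """
    df = _read_table(path, fmt)
    _require_columns(df, VOCAB_COLUMNS, "vocabulary")
    concepts = [
        TargetConcept(
            concept_id=row.concept_id,
            name=row.concept_name,
            vocabulary_id=row.vocabulary_id,
        )
        for row in df.itertuples()
    ]
    vocab_id = concepts[0].vocabulary_id if concepts else ""
    return Vocabulary(vocab_id, concepts)


def load_source_concepts(path: str | Path, fmt: str = "csv") -> list[SourceConcept]:
    """Load source concepts, sorted by frequency descending.

    Ties are broken by normalized name ascending so the review queue order
    is deterministic.  Negative frequencies and unknown domain tokens raise
    :class:`SchemaError`.
    """
    df = _read_table(path, fmt)
    _require_columns(df, SOURCE_COLUMNS, "source-concept")
    concepts = []
    for row in df.itertuples():
        try:
            freq = int(row.frequency)
        except ValueError as exc:
            raise SchemaError(f"non-integer frequency {row.frequency!r}") from exc
        if freq < 0:
            raise SchemaError(f"negative frequency {freq} for {row.raw_name!r}")
        try:
            domain = Domain(row.domain)
        except ValueError as exc:
            raise SchemaError(f"unknown domain token {row.domain!r}") from exc
        concepts.append(
            SourceConcept(
                raw_name=row.raw_name,
                site_id=row.site_id,
                domain=domain,
                frequency=freq,
            )
        )
    concepts.sort(key=lambda c: (-c.frequency, c.normalized_name))
    return concepts


def export_mappings(records: Iterable[MappingRecord], path: str | Path) -> None:
    """Write mapping records as a Usagi-style CSV.

    Validates the mapped-implies-target invariant on every record before any
    write, so a bad record never produces a partial file.
    """
    records = list(records)
    for rec in records:
        if (rec.status is MappingStatus.MAPPED) != (rec.target is not None):
            raise InvariantError(
                f"record for {rec.source.raw_name!r} violates the "
                "status/target invariant"
            )
    rows = []
    for rec in records:
        rows.append(
            {
                "source_name": rec.source.raw_name,
                "source_site": rec.source.site_id,
                "source_frequency": rec.source.frequency,
                "target_concept_id": rec.target.concept_id if rec.target else "",
                "target_name": rec.target.name if rec.target else "",
                "match_score": (
                    "" if rec.similarity_at_decision is None
                    else repr(float(rec.similarity_at_decision))
                ),
                "mapping_status": rec.status.value,
                "reviewer_id": rec.reviewer_id,
                "timestamp": rec.timestamp.isoformat(),
            }
        )
    df = pd.DataFrame(rows, columns=list(MAPPING_COLUMNS))
    df.to_csv(path, index=False)


def read_mappings(
    path: str | Path,
    vocabulary: Optional[Vocabulary] = None,
    domain: Domain = Domain.LAB_TEST,
) -> list[MappingRecord]:
    """Read a Usagi-style mapping CSV back into records.

    The table does not carry the source domain or the target vocabulary id;
    ``domain`` supplies the former and, when ``vocabulary`` is given, targets
    are resolved against it (unknown ids raise :class:`SchemaError`).
    Together with :func:`export_mappings` this round-trips valid records.
    """
    df = _read_table(path, "csv")
    _require_columns(df, MAPPING_COLUMNS, "mapping")
    records = []
    for row in df.itertuples():
        source = SourceConcept(
            raw_name=row.source_name,
            site_id=row.source_site,
            domain=domain,
            frequency=int(row.source_frequency),
        )
        status = MappingStatus(row.mapping_status)
        target: Optional[TargetConcept] = None
        if status is MappingStatus.MAPPED:
            if vocabulary is not None:
                if row.target_concept_id not in vocabulary:
                    raise SchemaError(
                        f"target {row.target_concept_id!r} not in vocabulary "
                        f"{vocabulary.vocabulary_id!r}"
                    )
                target = vocabulary.get(row.target_concept_id)
            else:
                target = TargetConcept(
                    concept_id=row.target_concept_id,
                    name=row.target_name,
                    vocabulary_id="",
                )
        score = float(row.match_score) if row.match_score != "" else None
        records.append(
            MappingRecord(
                source=source,
                status=status,
                target=target,
                similarity_at_decision=score,
                reviewer_id=row.reviewer_id,
                timestamp=datetime.fromisoformat(row.timestamp),
            )
        )
    return records
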