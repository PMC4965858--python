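"""Protein-acceptance and exclusion rules applied before quantitation.

Defaults encode the acceptance criteria of the analysis: identification
probability of at least 0.99, at least 2 unique peptides, and exclusion of
contaminants, reversed-database decoys and "cDNA-like" entries (detected by
a configurable description pattern). The probability rule uses >= 0.99 so
that records reported exactly at the 99% floor are retained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .report_io import CountMatrix, ProteinRecord

__all__ = ["FilterPolicy", "FilterReport", "flag_cdna_like", "apply_filters"]

DEFAULT_CDNA_PATTERN = "cDNA"

# attribution order for records failing several rules at once
RULE_DECOY = "decoy"
RULE_CONTAMINANT = "contaminant"
RULE_CDNA_LIKE = "cdna_like"
RULE_PROBABILITY = "probability"
RULE_UNIQUE_PEPTIDES = "unique_peptides"
RULE_ORDER = (
    RULE_DECOY,
    RULE_CONTAMINANT,
    RULE_CDNA_LIKE,
    RULE_PROBABILITY,
    RULE_UNIQUE_PEPTIDES,
)


@dataclass(frozen=True)
class FilterPolicy:
    min_unique_peptides: int = 2
    min_probability: float = 0.99
    exclude_contaminants: bool = True
    exclude_decoys: bool = True
    exclude_cdna_like: bool = True
    cdna_pattern: str = DEFAULT_CDNA_PATTERN

    def __post_init__(self) -> None:
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be a positive integer")
        if not 0.0 <= self.min_probability <= 1.0:
            raise ValueError("min_probability must lie in [0, 1]")

    @classmethod
    def disabled(cls) -> "FilterPolicy":
        """A policy under which filtering is the identity."""
        return cls(
            min_unique_peptides=1,
            min_probability=0.0,
            exclude_contaminants=False,
            exclude_decoys=False,
            exclude_cdna_like=False,
        )


@dataclass
class FilterReport:
    """Per-rule removal counts and the accessions removed by each rule."""

    removed: dict[str, list[str]] = field(
        default_factory=lambda: {rule: [] for rule in RULE_ORDER}
    )
    n_input: int = 0
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def counts(self) -> dict[str, int]:
        return {rule: len(accs) for rule, accs in self.removed.items()}

    def rows(self) -> list[tuple[str, str]]:
        return [(rule, acc) for rule in RULE_ORDER for acc in self.removed[rule]]


def _compile(pattern: str) -> re.Pattern[str]:
    try:
        return re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid cDNA-like pattern {pattern!r}: {exc}") from exc


def flag_cdna_like(
    records: Sequence["ProteinRecord"],
    pattern: str = DEFAULT_CDNA_PATTERN,
) -> list["ProteinRecord"]:
    """Return copies with ``is_cdna_like`` set where the description matches.

    Case-insensitive regular-expression search (the default pattern is a
    plain substring). Records already flagged stay flagged; idempotent.
    """
    compiled = _compile(pattern)
    return [
        replace(
            record,
            counts=dict(record.counts),
            is_cdna_like=record.is_cdna_like
            or bool(compiled.search(record.description)),
        )
        for record in records
    ]


def apply_filters(
    matrix: "CountMatrix",
    policy: FilterPolicy = FilterPolicy(),
) -> tuple["CountMatrix", FilterReport]:
    """Apply every enabled acceptance rule, in a fixed attribution order.

    Returns a new matrix of the retained records (original order, sample
    totals recomputed) and a report listing removals per rule. A record
    failing several rules is attributed to the first failing rule of
    decoy > contaminant > cdna-like > probability > unique-peptides.
    """
    from .report_io import CountMatrix  # local import avoids a cycle

    flagged = (
        flag_cdna_like(matrix.records, policy.cdna_pattern)
        if policy.exclude_cdna_like
        else list(matrix.records)
    )
    report = FilterReport(n_input=len(flagged))
    retained = []
    for record in flagged:
        if policy.exclude_decoys and record.is_decoy:
            report.removed[RULE_DECOY].append(record.accession)
        elif policy.exclude_contaminants and record.is_contaminant:
            report.removed[RULE_CONTAMINANT].append(record.accession)
        elif policy.exclude_cdna_like and record.is_cdna_like:
            report.removed[RULE_CDNA_LIKE].append(record.accession)
        elif record.protein_probability < policy.min_probability:
            report.removed[RULE_PROBABILITY].append(record.accession)
        elif record.unique_peptides < policy.min_unique_peptides:
            report.removed[RULE_UNIQUE_PEPTIDES].append(record.accession)
        else:
            retained.append(record)
    report.n_retained = len(retained)
    filtered = CountMatrix.from_records(retained, matrix.annotation)
    return filtered, report
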