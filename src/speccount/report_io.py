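"""Tabular I/O for spectral-count differential analysis.

Formats
-------
protein report
    Tab-separated, one header line. Canonical columns ``accession``, ``gene``,
    ``description``, ``unique_peptides``, ``probability``, optional boolean flag
    columns (``is_contaminant``, ``is_decoy``, ``is_cdna_like``) and one integer
    column per sample. A :class:`ReportDialect` maps vendor column names onto
    the canonical ones.
sample annotation
    Two-column TSV ``sample_id<TAB>group`` with a header line.
gene sets
    Standard GMT: ``name<TAB>description<TAB>member...``, one set per line.
differential table
    TSV emitted by :func:`write_differential_table`; round-trips losslessly
    through :func:`read_differential_table`.

Missing count cells are rejected rather than imputed: a zero must be explicit
because "unique to one cohort" classification hinges on true zeros.
All files are UTF-8 with "." as the decimal separator.
"""

from __future__ import annotations

import csv
import math
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .countstats import DifferentialRecord, GroupPool

__all__ = [
    "ProteinRecord",
    "SampleAnnotation",
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ReportDialect",
    "ReportFormatError",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_protein_report",
    "write_protein_report",
    "read_gmt",
    "write_gmt",
    "write_differential_table",
    "read_differential_table",
]


class ReportFormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _parse_bool(cell: str, *, row: int, column: str) -> bool:
    token = cell.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ReportFormatError(
        f"row {row}: cannot parse boolean {cell!r} in column {column!r}"
    )


@dataclass
class ProteinRecord:
    """One identified protein: per-sample significant spectral counts plus
    the identification metadata the acceptance filters act on."""

    accession: str
    gene_symbol: str = ""
    description: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    unique_peptides: int = 0
    protein_probability: float = 1.0
    is_contaminant: bool = False
    is_decoy: bool = False
    is_cdna_like: bool = False

    def validate(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        for sample, count in self.counts.items():
            if not isinstance(count, numbers.Integral) or isinstance(count, bool):
                raise ValueError(
                    f"{self.accession}: count for sample {sample!r} is not an integer"
                )
            if count < 0:
                raise ValueError(
                    f"{self.accession}: negative count {count} for sample {sample!r}"
                )
        if not 0.0 <= self.protein_probability <= 1.0:
            raise ValueError(
                f"{self.accession}: protein_probability "
                f"{self.protein_probability} outside [0, 1]"
            )
        if self.unique_peptides < 0:
            raise ValueError(f"{self.accession}: negative unique_peptides")

    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SampleAnnotation:
    """Membership of one sample in one of the two contrast groups."""

    sample_id: str
    group: str


@dataclass
class CountMatrix:
    """Proteins x samples integer count table with a two-group annotation.

    ``sample_totals`` always equals the per-sample column sums over the
    retained records (the normalisation denominators of the analysis).
    """

    records: list[ProteinRecord]
    annotation: list[SampleAnnotation]
    sample_totals: dict[str, int]

    @classmethod
    def from_records(
        cls,
        records: Sequence[ProteinRecord],
        annotation: Sequence[SampleAnnotation],
    ) -> "CountMatrix":
        matrix = cls(list(records), list(annotation), {})
        matrix.recompute_totals()
        matrix.validate()
        return matrix

    # -- structure ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotation]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.annotation:
            seen.setdefault(a.group, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [a.sample_id for a in self.annotation if a.group == group]

    def group_of(self, sample_id: str) -> str:
        for a in self.annotation:
            if a.sample_id == sample_id:
                return a.group
        raise KeyError(sample_id)

    def record_for(self, accession: str) -> ProteinRecord:
        for record in self.records:
            if record.accession == accession:
                return record
        raise KeyError(accession)

    def recompute_totals(self) -> None:
        totals = {sid: 0 for sid in self.sample_ids}
        for record in self.records:
            for sid, count in record.counts.items():
                totals[sid] = totals.get(sid, 0) + count
        self.sample_totals = {sid: totals.get(sid, 0) for sid in self.sample_ids}

    def validate(self) -> None:
        sample_set = set(self.sample_ids)
        if len(sample_set) != len(self.annotation):
            raise ValueError("duplicate sample ids in annotation")
        seen: set[str] = set()
        for record in self.records:
            record.validate()
            if record.accession in seen:
                raise ValueError(f"duplicate accession {record.accession!r}")
            seen.add(record.accession)
            if set(record.counts) != sample_set:
                raise ValueError(
                    f"{record.accession}: counts cover samples "
                    f"{sorted(record.counts)} but annotation has {sorted(sample_set)}"
                )
        for sid in self.sample_ids:
            column_sum = sum(r.counts[sid] for r in self.records)
            if column_sum != self.sample_totals.get(sid):
                raise ValueError(
                    f"sample_totals[{sid!r}] = {self.sample_totals.get(sid)} "
                    f"differs from column sum {column_sum}"
                )

    def subset(self, accessions: Iterable[str]) -> "CountMatrix":
        wanted = set(accessions)
        kept = [r for r in self.records if r.accession in wanted]
        return CountMatrix.from_records(kept, self.annotation)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene symbols for over-representation analysis."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        member_set = frozenset(m for m in members if m)
        if not member_set:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(name, description, member_set)


@dataclass(frozen=True)
class ReportDialect:
    """Column-name mapping from a vendor export to the canonical report."""

    accession: str = "accession"
    gene: str = "gene"
    description: str = "description"
    unique_peptides: str = "unique_peptides"
    probability: str = "probability"
    contaminant: str = "is_contaminant"
    decoy: str = "is_decoy"
    cdna_like: str = "is_cdna_like"

    def required_columns(self) -> tuple[str, ...]:
        return (
            self.accession,
            self.gene,
            self.description,
            self.unique_peptides,
            self.probability,
        )

    def flag_columns(self) -> tuple[str, ...]:
        return (self.contaminant, self.decoy, self.cdna_like)


DEFAULT_DIALECT = ReportDialect()


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_sample_annotation(path: Union[str, Path]) -> list[SampleAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotation: list[SampleAnnotation] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ReportFormatError(f"{path}: expected header 'sample_id\\tgroup'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ReportFormatError(f"{path}: line {lineno}: expected two columns")
            sample_id, group = row[0].strip(), row[1].strip()
            if not sample_id or not group:
                raise ReportFormatError(
                    f"{path}: line {lineno}: empty sample id or group"
                )
            if sample_id in seen:
                raise ReportFormatError(
                    f"{path}: duplicate sample id {sample_id!r} at line {lineno}"
                )
            seen.add(sample_id)
            annotation.append(SampleAnnotation(sample_id, group))
    if not annotation:
        raise ReportFormatError(f"{path}: no samples annotated")
    return annotation


def write_sample_annotation(
    annotation: Sequence[SampleAnnotation], path: Union[str, Path]
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "group"])
        for a in annotation:
            writer.writerow([a.sample_id, a.group])


# ---------------------------------------------------------------------------
# protein report
# ---------------------------------------------------------------------------

def read_protein_report(
    path: Union[str, Path],
    annotation: Union[str, Path, Sequence[SampleAnnotation]],
    dialect: ReportDialect | None = None,
) -> CountMatrix:
    """Read a protein identification report into a :class:`CountMatrix`.

    ``annotation`` may be a path to an annotation TSV or an already-parsed
    sequence. Sample columns are every header column not claimed by the
    dialect; each must be annotated, and every annotated sample must appear
    in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or DEFAULT_DIALECT
    if isinstance(annotation, (str, Path)):
        annotation = read_sample_annotation(annotation)
    annotation = list(annotation)
    annotated = {a.sample_id for a in annotation}

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ReportFormatError(f"{path}: empty file")
        header = [h.strip() for h in header]
        for column in dialect.required_columns():
            if column not in header:
                raise ReportFormatError(f"{path}: missing required column {column!r}")
        known = set(dialect.required_columns()) | set(dialect.flag_columns())
        sample_columns = [h for h in header if h not in known]
        unknown = [s for s in sample_columns if s not in annotated]
        if unknown:
            raise ReportFormatError(
                f"{path}: sample column(s) {unknown} absent from the annotation"
            )
        missing = sorted(annotated - set(sample_columns))
        if missing:
            raise ReportFormatError(
                f"{path}: annotated sample(s) {missing} absent from the report header"
            )
        index = {name: i for i, name in enumerate(header)}

        records: list[ProteinRecord] = []
        seen: dict[str, int] = {}
        duplicates: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ReportFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )

            def cell(column: str) -> str:
                return row[index[column]]

            accession = cell(dialect.accession).strip()
            if not accession:
                raise ReportFormatError(f"{path}: line {lineno}: missing accession")
            if accession in seen:
                duplicates.append(accession)
                continue
            seen[accession] = lineno

            counts: dict[str, int] = {}
            for sid in sample_columns:
                raw = cell(sid).strip()
                if raw == "":
                    raise ReportFormatError(
                        f"{path}: line {lineno}: missing count in column {sid!r} "
                        "(zeros must be explicit)"
                    )
                try:
                    value = int(raw)
                except ValueError as exc:
                    raise ReportFormatError(
                        f"{path}: line {lineno}: unparseable count {raw!r} "
                        f"in column {sid!r}"
                    ) from exc
                if value < 0:
                    raise ReportFormatError(
                        f"{path}: line {lineno}: negative count {value} "
                        f"in column {sid!r}"
                    )
                counts[sid] = value

            try:
                unique_peptides = int(cell(dialect.unique_peptides).strip() or "0")
                probability = float(cell(dialect.probability).strip() or "1.0")
            except ValueError as exc:
                raise ReportFormatError(
                    f"{path}: line {lineno}: unparseable metadata field"
                ) from exc

            record = ProteinRecord(
                accession=accession,
                gene_symbol=cell(dialect.gene).strip(),
                description=cell(dialect.description).strip(),
                counts=counts,
                unique_peptides=unique_peptides,
                protein_probability=probability,
                is_contaminant=(
                    _parse_bool(cell(dialect.contaminant), row=lineno,
                                column=dialect.contaminant)
                    if dialect.contaminant in index else False
                ),
                is_decoy=(
                    _parse_bool(cell(dialect.decoy), row=lineno,
                                column=dialect.decoy)
                    if dialect.decoy in index else False
                ),
                is_cdna_like=(
                    _parse_bool(cell(dialect.cdna_like), row=lineno,
                                column=dialect.cdna_like)
                    if dialect.cdna_like in index else False
                ),
            )
            record.validate()
            records.append(record)

        if duplicates:
            raise ReportFormatError(
                f"{path}: duplicate accession(s): {sorted(set(duplicates))}"
            )

    # keep annotation restricted to samples actually present (all of them here)
    return CountMatrix.from_records(records, annotation)


def write_protein_report(
    matrix: CountMatrix,
    path: Union[str, Path],
    dialect: ReportDialect | None = None,
) -> None:
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    sample_ids = matrix.sample_ids
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            list(dialect.required_columns())
            + list(dialect.flag_columns())
            + sample_ids
        )
        for record in matrix.records:
            writer.writerow(
                [
                    record.accession,
                    record.gene_symbol,
                    record.description,
                    record.unique_peptides,
                    repr(record.protein_probability),
                    str(record.is_contaminant).lower(),
                    str(record.is_decoy).lower(),
                    str(record.is_cdna_like).lower(),
                ]
                + [record.counts[sid] for sid in sample_ids]
            )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ReportFormatError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    "and at least one member"
                )
            name, description = fields[0].strip(), fields[1]
            try:
                collection.add(name, description, (m.strip() for m in fields[2:]))
            except ValueError as exc:
                raise ReportFormatError(f"{path}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for gene_set in collection:
            members = "\t".join(sorted(gene_set.members))
            handle.write(f"{gene_set.name}\t{gene_set.description}\t{members}\n")


# ---------------------------------------------------------------------------
# differential table
# ---------------------------------------------------------------------------

_DIFF_COLUMNS = [
    "accession",
    "gene",
    "description",
    "n_ref",
    "n_cmp",
    "N_ref",
    "N_cmp",
    "present_ref",
    "present_cmp",
    "raw_ratio",
    "rsc",
    "p_value",
    "q_value",
    "selected",
    "category",
]


def _fmt_float(value: float) -> str:
    # repr() gives the shortest string that round-trips exactly
    return repr(float(value))


def write_differential_table(
    records: Sequence[DifferentialRecord], path: Union[str, Path]
) -> None:
    """Write one row per protein; stable column order; lossless round-trip."""
    path = Path(path)
    for record in records:
        for label, value in (("raw_ratio", record.raw_ratio),
                             ("rsc", record.rsc),
                             ("p_value", record.p_value)):
            if not math.isfinite(value):
                raise ValueError(
                    f"{record.accession}: non-finite {label} {value!r}"
                )
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_DIFF_COLUMNS)
        for record in records:
            pool = record.pool
            writer.writerow(
                [
                    record.accession,
                    record.gene_symbol,
                    record.description,
                    pool.n_ref,
                    pool.n_cmp,
                    pool.N_ref,
                    pool.N_cmp,
                    pool.present_ref,
                    pool.present_cmp,
                    _fmt_float(record.raw_ratio),
                    _fmt_float(record.rsc),
                    _fmt_float(record.p_value),
                    _fmt_float(record.q_value) if math.isfinite(record.q_value)
                    else "nan",
                    str(record.selected).lower(),
                    record.category or "",
                ]
            )


def read_differential_table(path: Union[str, Path]) -> list[DifferentialRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[DifferentialRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != _DIFF_COLUMNS:
            raise ReportFormatError(
                f"{path}: unexpected differential-table header {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_DIFF_COLUMNS):
                raise ReportFormatError(
                    f"{path}: line {lineno}: expected {len(_DIFF_COLUMNS)} fields"
                )
            values = dict(zip(_DIFF_COLUMNS, row))
            pool = GroupPool(
                n_ref=int(values["n_ref"]),
                n_cmp=int(values["n_cmp"]),
                N_ref=int(values["N_ref"]),
                N_cmp=int(values["N_cmp"]),
                present_ref=int(values["present_ref"]),
                present_cmp=int(values["present_cmp"]),
            )
            records.append(
                DifferentialRecord(
                    accession=values["accession"],
                    gene_symbol=values["gene"],
                    description=values["description"],
                    pool=pool,
                    raw_ratio=float(values["raw_ratio"]),
                    rsc=float(values["rsc"]),
                    p_value=float(values["p_value"]),
                    q_value=float(values["q_value"]),
                    selected=values["selected"] == "true",
                    category=values["category"] or None,
                )
            )
    return records
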