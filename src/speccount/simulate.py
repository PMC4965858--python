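"""Synthetic two-cohort protein reports with planted ground truth.

Counts follow a gamma-mixed Poisson (negative-binomial-like) model: protein
i in sample s of group g has rate ``w_i * depth_g * fold_i``, where the
relative abundances ``w`` are lognormal and normalised, group depths encode
a between-group sequencing-depth imbalance, and ``fold_i`` multiplies the
comparison-group rate for planted effects. Cohort-unique proteins have zero
rate in the other cohort; dropout zeroes individual cells. Injected
nuisance rows (contaminants, decoys, cDNA-like descriptions) exercise the
identification filters end to end.

Everything is reproducible from the seed, and the emitted files use the
same dialect the report reader consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .report_io import (
    CountMatrix,
    ProteinRecord,
    SampleAnnotation,
    write_protein_report,
    write_sample_annotation,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "GeneratedDataset",
    "RecoveryMetrics",
    "generate_matrix",
    "generate",
    "recovery_report",
]

TRUTH_NULL = "null"
TRUTH_DE_UP = "de-up"
TRUTH_DE_DOWN = "de-down"
TRUTH_UNIQUE_REF = "unique_ref"
TRUTH_UNIQUE_CMP = "unique_cmp"

_TRUTH_COLUMNS = ["accession", "category", "true_fold", "nuisance"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 1000
    samples_per_group: int = 4
    mean_depth: float = 20_000.0
    #: reference / comparison expected-depth ratio
    depth_ratio: float = 1.12
    #: negative-binomial overdispersion alpha, var = mu + alpha * mu^2
    dispersion: float = 0.1
    #: sigma of the lognormal relative-abundance spread
    abundance_sigma: float = 1.0
    frac_de: float = 0.1
    fold_range: tuple[float, float] = (2.0, 8.0)
    frac_unique_ref: float = 0.05
    frac_unique_cmp: float = 0.05
    dropout: float = 0.0
    n_contaminants: int = 0
    n_decoys: int = 0
    n_cdna_like: int = 0
    seed: int = 0
    ref_label: str = "REF"
    cmp_label: str = "CMP"

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be non-negative")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be positive")
        if self.mean_depth <= 0 or self.depth_ratio <= 0:
            raise ValueError("depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for name in ("frac_de", "frac_unique_ref", "frac_unique_cmp", "dropout"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_de + self.frac_unique_ref + self.frac_unique_cmp > 1.0:
            raise ValueError("planted fractions sum above 1 (infeasible)")
        lo, hi = self.fold_range
        if not (lo >= 1.0 and hi >= lo):
            raise ValueError("fold_range must satisfy 1 <= lo <= hi")
        if min(self.n_contaminants, self.n_decoys, self.n_cdna_like) < 0:
            raise ValueError("nuisance row counts must be non-negative")
        if self.ref_label == self.cmp_label:
            raise ValueError("group labels must differ")


#: one truth row per generated report row
SyntheticTruth = pd.DataFrame


@dataclass
class GeneratedDataset:
    report_path: Path
    annotation_path: Path
    truth_path: Path
    truth: SyntheticTruth


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    false_discovery_proportion: float
    sign_agreement: float
    n_true_effects: int
    n_selected: int


def _sample_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-mixed Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)  # scale 0 where mu == 0
    return rng.poisson(lam)


def generate_matrix(config: SyntheticConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate the count matrix and its ground-truth table in memory."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    m = config.samples_per_group

    annotation = [
        SampleAnnotation(f"{config.ref_label}{i + 1}", config.ref_label)
        for i in range(m)
    ] + [
        SampleAnnotation(f"{config.cmp_label}{i + 1}", config.cmp_label)
        for i in range(m)
    ]
    sample_ids = [a.sample_id for a in annotation]

    n_de = round(config.frac_de * n)
    n_up = n_de // 2 + n_de % 2
    n_down = n_de - n_up
    n_uref = round(config.frac_unique_ref * n)
    n_ucmp = round(config.frac_unique_cmp * n)
    if n_de + n_uref + n_ucmp > n:
        raise ValueError("planted fractions infeasible for this n_proteins")

    categories = np.array(
        [TRUTH_DE_UP] * n_up
        + [TRUTH_DE_DOWN] * n_down
        + [TRUTH_UNIQUE_REF] * n_uref
        + [TRUTH_UNIQUE_CMP] * n_ucmp
        + [TRUTH_NULL] * (n - n_de - n_uref - n_ucmp),
        dtype=object,
    )

    lo, hi = config.fold_range
    fold = np.ones(n)
    fold[: n_up] = rng.uniform(lo, hi, n_up)
    fold[n_up : n_up + n_down] = 1.0 / rng.uniform(lo, hi, n_down)

    if n > 0:
        w = rng.lognormal(0.0, config.abundance_sigma, n)
        w = w / w.sum()
    else:
        w = np.empty(0)

    r = config.depth_ratio
    depth_ref = config.mean_depth * 2.0 * r / (1.0 + r)
    depth_cmp = config.mean_depth * 2.0 / (1.0 + r)

    mu = np.empty((n, 2 * m))
    mu[:, :m] = np.outer(w * depth_ref, np.ones(m))
    mu[:, m:] = np.outer(w * depth_cmp * fold, np.ones(m))
    is_uref = categories == TRUTH_UNIQUE_REF
    is_ucmp = categories == TRUTH_UNIQUE_CMP
    mu[is_uref, m:] = 0.0
    mu[is_ucmp, :m] = 0.0

    counts = _sample_counts(rng, mu, config.dispersion)
    if config.dropout > 0:
        counts = np.where(
            rng.random(counts.shape) < config.dropout, 0, counts
        )

    width = max(4, len(str(max(n, 1))))
    records: list[ProteinRecord] = []
    truth_rows: list[tuple[str, str, float, bool]] = []
    for i in range(n):
        accession = f"SYN{i:0{width}d}"
        records.append(
            ProteinRecord(
                accession=accession,
                gene_symbol=f"GENE{i:0{width}d}",
                description=f"synthetic protein {i}",
                counts={sid: int(c) for sid, c in zip(sample_ids, counts[i])},
                unique_peptides=2 + int(rng.poisson(4)),
                protein_probability=1.0,
            )
        )
        truth_rows.append((accession, str(categories[i]), float(fold[i]), False))

    # nuisance rows: drawn like a null protein of median abundance
    nuisance_mu = float(np.median(w)) if n else 1e-3
    nuisance_specs = (
        [("CONT", "Keratin-like laboratory contaminant", dict(is_contaminant=True))]
        * config.n_contaminants
        + [("REVSYN", "reversed-sequence decoy entry", dict(is_decoy=True))]
        * config.n_decoys
        + [("CDNA", "cDNA FLJ synthetic clone, highly similar to nothing", {})]
        * config.n_cdna_like
    )
    for j, (prefix, description, flags) in enumerate(nuisance_specs):
        row_mu = np.empty(2 * m)
        row_mu[:m] = nuisance_mu * depth_ref
        row_mu[m:] = nuisance_mu * depth_cmp
        row_counts = _sample_counts(rng, row_mu, config.dispersion)
        accession = f"{prefix}{j:03d}"
        records.append(
            ProteinRecord(
                accession=accession,
                gene_symbol="",
                description=description,
                counts={sid: int(c) for sid, c in zip(sample_ids, row_counts)},
                unique_peptides=2 + int(rng.poisson(2)),
                protein_probability=1.0,
                **flags,
            )
        )
        truth_rows.append((accession, TRUTH_NULL, 1.0, True))

    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    matrix = CountMatrix.from_records(records, annotation)
    return matrix, truth


def generate(
    config: SyntheticConfig, out_dir: Union[str, Path]
) -> GeneratedDataset:
    """Generate and write the report, annotation and truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_matrix(config)
    report_path = out_dir / "report.tsv"
    annotation_path = out_dir / "annotation.tsv"
    truth_path = out_dir / "truth.tsv"
    write_protein_report(matrix, report_path)
    write_sample_annotation(matrix.annotation, annotation_path)
    truth.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    return GeneratedDataset(
        report_path=report_path,
        annotation_path=annotation_path,
        truth_path=truth_path,
        truth=truth,
    )


_POSITIVE = {TRUTH_DE_UP, TRUTH_UNIQUE_CMP}
_NEGATIVE = {TRUTH_DE_DOWN, TRUTH_UNIQUE_REF}


def recovery_report(truth: SyntheticTruth, results: Sequence) -> RecoveryMetrics:
    """Recovery of planted effects by a differential analysis.

    Computed over non-nuisance rows only. Result accessions must be a
    subset of the truth's non-nuisance accessions (rows the analysis
    legitimately dropped, e.g. zero counts everywhere, count as unselected).
    """
    non_nuisance = truth[~truth["nuisance"].astype(bool)]
    known = set(non_nuisance["accession"])
    category = dict(zip(non_nuisance["accession"], non_nuisance["category"]))

    unknown = [r.accession for r in results if r.accession not in known]
    if unknown:
        raise ValueError(
            f"result rows not present in the truth table: {sorted(unknown)[:10]}"
        )

    selected = [r for r in results if r.selected]
    n_true = sum(c != TRUTH_NULL for c in category.values())
    true_selected = [s for s in selected if category[s.accession] != TRUTH_NULL]
    null_selected = [s for s in selected if category[s.accession] == TRUTH_NULL]

    agree = 0
    for record in true_selected:
        wanted = 1 if category[record.accession] in _POSITIVE else -1
        if (record.rsc > 0) == (wanted > 0):
            agree += 1

    return RecoveryMetrics(
        sensitivity=len(true_selected) / n_true if n_true else 1.0,
        false_discovery_proportion=(
            len(null_selected) / len(selected) if selected else 0.0
        ),
        sign_agreement=agree / len(true_selected) if true_selected else 1.0,
        n_true_effects=n_true,
        n_selected=len(selected),
    )
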