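"""Bundled two-cohort benchmark table and its reproduction.

The fixture ``data/two_cohort_benchmark.tsv`` transcribes thirty published
(pooled count, signed ratio) pairs from a two-cohort spectral-counting
study: ten proteins unique to the reference cohort, ten unique to the
comparison cohort, and ten detected in both. The group totals behind those
ratios were not published; :func:`calibrate` recovers the single
between-group scale by least squares on the common (both-cohorts) subset,
after which every unique-protein signed ratio reproduces to one decimal.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .countstats import PseudocountConfig, calibrate_total_ratio, signed_ratio

__all__ = ["load_benchmark_table", "calibrate", "reproduce_benchmark"]

SUBSET_REF_UNIQUE = "ref_unique"
SUBSET_CMP_UNIQUE = "cmp_unique"
SUBSET_COMMON = "common_enriched"

_CALIBRATION_SUBSET = SUBSET_COMMON


def load_benchmark_table() -> pd.DataFrame:
    """The bundled fixture as a data frame (one row per protein)."""
    with resources.files("speccount.data").joinpath(
        "two_cohort_benchmark.tsv"
    ).open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t")


def calibrate(
    table: pd.DataFrame | None = None,
    cfg: PseudocountConfig = PseudocountConfig(),
) -> float:
    """Least-squares group-total ratio from the common-subset rows."""
    if table is None:
        table = load_benchmark_table()
    rows = table[table["subset"] == _CALIBRATION_SUBSET]
    return calibrate_total_ratio(
        rows[["n_ref", "n_cmp", "expected_rsc"]].itertuples(index=False),
        cfg,
    )


def reproduce_benchmark(
    cfg: PseudocountConfig = PseudocountConfig(),
) -> pd.DataFrame:
    """Recompute the signed ratio for every fixture row.

    Adds ``total_ratio`` (the calibrated scale), ``computed_rsc`` and
    ``abs_error`` columns to the fixture table.
    """
    table = load_benchmark_table().copy()
    ratio = calibrate(table, cfg)
    computed = [
        signed_ratio(row.n_ref, row.n_cmp, ratio, cfg.f)[1]
        for row in table.itertuples(index=False)
    ]
    table["total_ratio"] = ratio
    table["computed_rsc"] = computed
    table["abs_error"] = (table["computed_rsc"] - table["expected_rsc"]).abs()
    return table
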