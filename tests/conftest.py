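"""Shared fixtures and independent test-side oracles.

The oracles deliberately use different routes than the package: exact
integer arithmetic for the two-sided exact test, a naive quadratic step-up
for the multiplicity adjustment, and textbook covariance formulas for
correlation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from speccount import CountMatrix, ProteinRecord, SampleAnnotation


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(n_ref: int, N_ref: int, n_cmp: int, N_cmp: int) -> float:
    """Exhaustive enumeration with exact rational arithmetic.

    Sums hypergeometric probabilities of every table sharing the margins
    whose point probability is <= that of the observed table (exact tie
    detection via integer numerators).
    """
    total = N_ref + N_cmp
    m = n_ref + n_cmp
    if total == 0 or m == 0 or m == total or N_ref == 0 or N_cmp == 0:
        return 1.0
    denominator = comb(total, m)
    numerators = {
        k: comb(N_ref, k) * comb(N_cmp, m - k)
        for k in range(max(0, m - N_cmp), min(m, N_ref) + 1)
    }
    observed = numerators[n_ref]
    total_num = sum(num for num in numerators.values() if num <= observed)
    return float(Fraction(total_num, denominator))


def bh_oracle(p_values) -> list[float]:
    """Naive quadratic-time step-up: q_i = min_{j >= rank(i)} p_(j) * m / j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def pearson_oracle(x, y) -> float:
    """Plain covariance-formula correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def two_group_annotation() -> list[SampleAnnotation]:
    return [
        SampleAnnotation("R1", "REF"),
        SampleAnnotation("R2", "REF"),
        SampleAnnotation("C1", "CMP"),
        SampleAnnotation("C2", "CMP"),
    ]


def make_matrix(rows: dict[str, list[int]], annotation) -> CountMatrix:
    """rows: accession -> counts in annotation order."""
    sample_ids = [a.sample_id for a in annotation]
    records = [
        ProteinRecord(
            accession=acc,
            gene_symbol=f"g_{acc}",
            description=f"protein {acc}",
            counts=dict(zip(sample_ids, counts)),
            unique_peptides=3,
            protein_probability=1.0,
        )
        for acc, counts in rows.items()
    ]
    return CountMatrix.from_records(records, annotation)


@pytest.fixture
def small_matrix(two_group_annotation) -> CountMatrix:
    return make_matrix(
        {
            "P1": [5, 5, 0, 0],
            "P2": [1, 2, 8, 9],
            "P3": [0, 0, 4, 6],
            "P4": [3, 3, 3, 3],
        },
        two_group_annotation,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160729)
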