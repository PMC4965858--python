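"""Sample-level structure analytics: correlation, clustering, overlap.

Per-sample protein count vectors are optionally depth-normalised
(count / sample total, rescaled by the median total) and log2(x+1)
transformed before correlating. Agglomerative clustering runs on the
distance 1 - correlation and the resulting tree serialises to Newick.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

if TYPE_CHECKING:  # pragma: no cover
    from .report_io import CountMatrix

__all__ = [
    "CorrelationMatrix",
    "LinkageTree",
    "correlation_matrix",
    "cluster_samples",
    "to_newick",
    "overlap_counts",
]

TRANSFORM_NONE = "none"
TRANSFORM_LOG2P1 = "log2p1-normalized"


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation of per-sample count profiles."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"correlation matrix shape {self.values.shape} does not match "
                f"{n} samples"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not unit")


@dataclass
class LinkageTree:
    """Rooted binary tree over sample leaves (hierarchical clustering result).

    ``merges`` is a standard (n-1) x 4 linkage matrix; merge heights are
    non-decreasing from leaves to root.
    """

    labels: list[str]
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if n >= 2 and self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")
        heights = self.merges[:, 2] if self.merges.size else np.empty(0)
        if heights.size and np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")


def _count_array(matrix: "CountMatrix") -> tuple[np.ndarray, list[str]]:
    sample_ids = matrix.sample_ids
    data = np.array(
        [[record.counts[s] for s in sample_ids] for record in matrix.records],
        dtype=float,
    )
    if data.size == 0:
        data = data.reshape(0, len(sample_ids))
    return data, sample_ids


def correlation_matrix(
    matrix: "CountMatrix",
    method: str = "pearson",
    transform: str = TRANSFORM_LOG2P1,
    include_group_pools: bool = False,
) -> CorrelationMatrix:
    """Pairwise correlation of per-sample protein count vectors.

    ``include_group_pools`` appends one pooled pseudo-sample per group
    (sum of the group's counts), mirroring "combined" columns in sample-level
    similarity displays.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if transform not in (TRANSFORM_NONE, TRANSFORM_LOG2P1):
        raise ValueError(f"unknown transform {transform!r}")
    data, sample_ids = _count_array(matrix)
    labels = list(sample_ids)
    if include_group_pools:
        for group in matrix.groups:
            cols = [sample_ids.index(s) for s in matrix.samples_in(group)]
            data = np.column_stack([data, data[:, cols].sum(axis=1)])
            labels.append(f"{group}_combined")
    if data.shape[1] < 2:
        raise ValueError("need at least two samples to correlate")
    if data.shape[0] < 2:
        raise ValueError("need at least two proteins to correlate samples")

    if transform == TRANSFORM_LOG2P1:
        totals = data.sum(axis=0)
        zero_depth = [labels[i] for i in np.nonzero(totals == 0)[0]]
        if zero_depth:
            raise ValueError(f"sample(s) with zero total counts: {zero_depth}")
        scale = float(np.median(totals))
        data = np.log2(data / totals * scale + 1.0)

    constant = [
        labels[i] for i in range(data.shape[1]) if np.ptp(data[:, i]) == 0
    ]
    if constant:
        raise ValueError(
            f"constant sample profile(s) after transform: {constant}"
        )
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 0, data)
    values = np.corrcoef(data, rowvar=False)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(sample_ids=labels, values=values)


def cluster_samples(
    corr: CorrelationMatrix, linkage: str = "average"
) -> LinkageTree:
    """Agglomerative clustering on the distance 1 - correlation."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    distances = 1.0 - corr.values
    distances = np.clip((distances + distances.T) / 2.0, 0.0, None)
    np.fill_diagonal(distances, 0.0)
    condensed = squareform(distances, checks=False)
    merges = scipy_linkage(condensed, method=linkage)
    return LinkageTree(labels=list(corr.sample_ids), merges=merges)


def _safe_label(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


def to_newick(tree: LinkageTree) -> str:
    """Serialise as Newick with ultrametric branch lengths.

    A node merged at height H places each child at H/2 from the root side,
    so the branch to a child merged at height h has length (H - h) / 2
    (leaves have h = 0); two leaves joined at height 0.4 give
    ``(A:0.2,B:0.2);``.
    """
    if len(tree.labels) == 1:
        return f"{_safe_label(tree.labels[0])}:0;"
    root = to_tree(tree.merges)

    def render(node) -> str:
        if node.is_leaf():
            return _safe_label(tree.labels[node.id])
        parts = []
        for child in (node.left, node.right):
            length = (node.dist - child.dist) / 2.0
            parts.append(f"{render(child)}:{length:.10g}")
        return "(" + ",".join(parts) + ")"

    return render(root) + ";"


def overlap_counts(
    matrix: "CountMatrix",
    ref_group: str | None = None,
    cmp_group: str | None = None,
) -> dict:
    """Detection overlap summary across the two cohorts.

    Per group: proteins detected (count > 0) in at least one sample and in
    every sample; across groups: intersection and group-exclusive counts.
    """
    from .countstats import resolve_groups

    ref_group, cmp_group = resolve_groups(matrix, ref_group, cmp_group)
    summary: dict = {"groups": {}}
    detected: dict[str, set[str]] = {}
    for group in (ref_group, cmp_group):
        samples = matrix.samples_in(group)
        any_set = {
            r.accession
            for r in matrix.records
            if any(r.counts[s] > 0 for s in samples)
        }
        all_set = {
            r.accession
            for r in matrix.records
            if all(r.counts[s] > 0 for s in samples)
        }
        detected[group] = any_set
        summary["groups"][group] = {
            "detected_any": len(any_set),
            "detected_all": len(all_set),
        }
    both = detected[ref_group] & detected[cmp_group]
    summary["intersection"] = len(both)
    summary["ref_only"] = len(detected[ref_group] - detected[cmp_group])
    summary["cmp_only"] = len(detected[cmp_group] - detected[ref_group])
    summary["ref_group"] = ref_group
    summary["cmp_group"] = cmp_group
    return summary
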