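"""Gene-set over-representation analysis against a user-supplied universe.

The enrichment p of one set is the upper-tail hypergeometric probability of
drawing at least the observed overlap when sampling the query from the
universe, i.e. the one-sided Fisher exact p of the corresponding 2x2 table.
The universe defaults (at pipeline level) to all post-filter identified
proteins, the only universe the pipeline can know.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from scipy.stats import hypergeom

from .countstats import bh_adjust

if TYPE_CHECKING:  # pragma: no cover
    from .countstats import DifferentialRecord
    from .report_io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "overrepresentation", "build_query_from_differential"]

DIRECTION_ENRICHED = "enriched"
DIRECTION_DIMINISHED = "diminished"
DIRECTION_BOTH = "both"


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float
    members_hit: tuple[str, ...]


def overrepresentation(
    query: Iterable[str],
    sets: "GeneSetCollection",
    universe: Iterable[str],
) -> list[EnrichmentRecord]:
    """Test every gene set for over-representation of ``query``.

    Query symbols outside the universe are reported and dropped. Sets are
    intersected with the universe; every set retaining at least one member
    is tested (the BH family), but only sets overlapping the query are
    emitted, sorted by p ascending then set name.
    """
    universe_set = {g for g in universe if g}
    if not universe_set:
        raise ValueError("universe is empty")
    query_all = {g for g in query if g}
    if not query_all:
        raise ValueError("query is empty")
    outside = query_all - universe_set
    if outside:
        logger.warning(
            "dropping %d query symbol(s) outside the universe: %s",
            len(outside),
            sorted(outside)[:10],
        )
    query_set = query_all & universe_set
    if not query_set:
        raise ValueError("no query symbols remain inside the universe")

    U, Q = len(universe_set), len(query_set)
    tested: list[tuple[str, int, int, tuple[str, ...], float]] = []
    for gene_set in sets:
        members = gene_set.members & universe_set
        if not members:
            continue
        hits = tuple(sorted(members & query_set))
        K = len(members)
        k = len(hits)
        # P(X >= k) for X ~ Hypergeom(U, K, Q)
        p = float(hypergeom.sf(k - 1, U, K, Q)) if k > 0 else 1.0
        p = min(max(p, 0.0), 1.0) or 1e-300
        tested.append((gene_set.name, k, K, hits, p))

    if not tested:
        return []
    q_values = bh_adjust([t[4] for t in tested])
    records = [
        EnrichmentRecord(
            set_name=name,
            overlap=k,
            set_size=K,
            query_size=Q,
            universe_size=U,
            p_value=p,
            q_value=float(q),
            members_hit=hits,
        )
        for (name, k, K, hits, p), q in zip(tested, q_values)
        if k >= 1
    ]
    records.sort(key=lambda r: (r.p_value, r.set_name))
    return records


def build_query_from_differential(
    records: Sequence["DifferentialRecord"],
    direction: str = DIRECTION_ENRICHED,
) -> set[str]:
    """Gene symbols of the selected records matching ``direction``.

    ``enriched``: positive signed ratio (including comparison-unique);
    ``diminished``: negative (including reference-unique); ``both``: all
    selected. Empty symbols are dropped with a warning; duplicates collapse.
    """
    if direction not in (DIRECTION_ENRICHED, DIRECTION_DIMINISHED, DIRECTION_BOTH):
        raise ValueError(f"unknown direction {direction!r}")
    symbols: set[str] = set()
    n_empty = 0
    for record in records:
        if not record.selected:
            continue
        if direction == DIRECTION_ENRICHED and record.rsc <= 0:
            continue
        if direction == DIRECTION_DIMINISHED and record.rsc >= 0:
            continue
        if not record.gene_symbol:
            n_empty += 1
            continue
        symbols.add(record.gene_symbol)
    if n_empty:
        logger.warning("dropped %d selected record(s) with empty gene symbol", n_empty)
    return symbols
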