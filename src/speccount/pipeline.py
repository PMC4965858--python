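"""End-to-end orchestration: filter -> pool -> ratio -> exact test -> BH ->
selection -> partition -> presence -> cohort structure -> enrichment.

Outputs are deterministic for fixed inputs and configuration: the run
directory receives the differential table, partition and overlap
summaries, presence breakdowns, correlation matrix, Newick tree, optional
enrichment table, the filter report and a machine-readable manifest with
stage counts and the data-derived group-total ratio.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from . import __version__
from .cohort import cluster_samples, correlation_matrix, overlap_counts, to_newick
from .countstats import (
    PseudocountConfig,
    SelectionPolicy,
    categorize,
    differential_analysis,
    presence_breakdown,
)
from .enrich import build_query_from_differential, overrepresentation
from .filters import FilterPolicy, apply_filters
from .report_io import (
    read_gmt,
    read_protein_report,
    read_sample_annotation,
    write_differential_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    report: Path
    annotation: Path
    out_dir: Path
    ref_group: str | None = None
    cmp_group: str | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    pseudocount: PseudocountConfig = field(default_factory=PseudocountConfig)
    selection: SelectionPolicy = field(default_factory=SelectionPolicy)
    correlation_method: str = "pearson"
    correlation_transform: str = "log2p1-normalized"
    include_group_pools: bool = False
    linkage: str = "average"
    gene_sets: Path | None = None
    enrich_direction: str = "enriched"
    seed: int = 0

    def to_mapping(self) -> dict:
        data = dataclasses.asdict(self)
        for key in ("report", "annotation", "out_dir", "gene_sets"):
            if data[key] is not None:
                data[key] = str(data[key])
        return data

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        data = dict(mapping)
        for key, klass in (
            ("filter_policy", FilterPolicy),
            ("pseudocount", PseudocountConfig),
            ("selection", SelectionPolicy),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = klass(**data[key])
        for key in ("report", "annotation", "out_dir", "gene_sets"):
            if data.get(key) is not None:
                data[key] = Path(data[key])
        return cls(**data)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a pipeline configuration from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        mapping = yaml.safe_load(text)
    else:
        mapping = json.loads(text)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return PipelineConfig.from_mapping(mapping)


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the run artifacts; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_mapping(),
        "stages": {},
    }

    def stage(name):
        def run(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_json(manifest, out_dir / "manifest.json")
                raise PipelineStageError(name, exc) from exc

        return run

    # ---- load ------------------------------------------------------------
    annotation = stage("load")(read_sample_annotation, config.annotation)
    matrix = stage("load")(read_protein_report, config.report, annotation)
    manifest["stages"]["load"] = {
        "n_records": len(matrix.records),
        "n_samples": len(matrix.annotation),
        "groups": matrix.groups,
    }

    # ---- filter ----------------------------------------------------------
    filtered, filter_report = stage("filter")(
        apply_filters, matrix, config.filter_policy
    )
    manifest["stages"]["filter"] = {
        "n_input": filter_report.n_input,
        "n_retained": filter_report.n_retained,
        "n_removed": filter_report.n_removed,
        "removed_per_rule": filter_report.counts(),
    }
    with (out_dir / "filter_report.tsv").open("w", encoding="utf-8") as handle:
        handle.write("rule\taccession\n")
        for rule, accession in filter_report.rows():
            handle.write(f"{rule}\t{accession}\n")

    # ---- differential ----------------------------------------------------
    records, dropped = stage("differential")(
        differential_analysis,
        filtered,
        config.ref_group,
        config.cmp_group,
        config.pseudocount,
        config.selection,
    )
    selected = [r for r in records if r.selected]
    partition = categorize(selected) if selected else None
    if records:
        pool = records[0].pool
        manifest["total_ratio"] = pool.N_ref / pool.N_cmp
        logger.info("data-derived group-total ratio: %.4f", manifest["total_ratio"])
    manifest["stages"]["differential"] = {
        "n_tested": len(records),
        "n_dropped_zero": len(dropped),
        "n_selected": len(selected),
    }
    write_differential_table(records, out_dir / "differential.tsv")
    partition_payload = {
        "n_selected": len(selected),
        "partition": partition.as_dict() if partition else {},
    }
    _write_json(partition_payload, out_dir / "partition.json")

    # ---- presence breakdown ---------------------------------------------
    from .countstats import resolve_groups

    ref_group, cmp_group = resolve_groups(filtered, config.ref_group, config.cmp_group)
    presence_payload = {}
    for direction, subset in (
        ("enriched", [r.accession for r in selected if r.rsc > 0]),
        ("diminished", [r.accession for r in selected if r.rsc < 0]),
    ):
        entry = {}
        for group in (ref_group, cmp_group):
            if subset:
                breakdown = stage("presence")(
                    presence_breakdown, filtered, subset, group
                )
                entry[group] = {
                    "fractions": {str(k): v for k, v in breakdown.fractions.items()},
                    "n_undetected": len(breakdown.undetected),
                }
            else:
                entry[group] = {"fractions": {}, "n_undetected": 0}
        presence_payload[direction] = entry
    _write_json(presence_payload, out_dir / "presence.json")

    # ---- cohort structure ------------------------------------------------
    corr = stage("cohort")(
        correlation_matrix,
        filtered,
        config.correlation_method,
        config.correlation_transform,
        config.include_group_pools,
    )
    with (out_dir / "correlation.tsv").open("w", encoding="utf-8") as handle:
        handle.write("sample\t" + "\t".join(corr.sample_ids) + "\n")
        for label, row in zip(corr.sample_ids, corr.values):
            handle.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    tree = stage("cohort")(cluster_samples, corr, config.linkage)
    (out_dir / "tree.nwk").write_text(to_newick(tree) + "\n", encoding="utf-8")
    overlap = stage("cohort")(
        overlap_counts, filtered, config.ref_group, config.cmp_group
    )
    _write_json(overlap, out_dir / "overlap.json")
    manifest["stages"]["cohort"] = {
        "n_samples_correlated": len(corr.sample_ids),
        "overlap": overlap,
    }

    # ---- enrichment ------------------------------------------------------
    if config.gene_sets is not None:
        sets = stage("enrichment")(read_gmt, config.gene_sets)
        query = build_query_from_differential(selected, config.enrich_direction)
        universe = {r.gene_symbol for r in filtered.records if r.gene_symbol}
        if query:
            enrichment = stage("enrichment")(
                overrepresentation, query, sets, universe
            )
        else:
            enrichment = []
        with (out_dir / "enrichment.tsv").open("w", encoding="utf-8") as handle:
            handle.write(
                "set_name\toverlap\tset_size\tquery_size\tuniverse_size"
                "\tp_value\tq_value\tmembers_hit\n"
            )
            for record in enrichment:
                handle.write(
                    f"{record.set_name}\t{record.overlap}\t{record.set_size}"
                    f"\t{record.query_size}\t{record.universe_size}"
                    f"\t{record.p_value!r}\t{record.q_value!r}"
                    f"\t{','.join(record.members_hit)}\n"
                )
        manifest["stages"]["enrichment"] = {
            "n_sets": len(sets),
            "n_query": len(query),
            "n_emitted": len(enrichment),
        }

    _write_json(manifest, out_dir / "manifest.json")
    return manifest
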