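"""End-to-end orchestration: filter -> ordinate -> vectors -> compare -> analyze.

Every stage writes plain TSV (Newick for trees) into the output
directory and the run ends with a JSON manifest mapping each artifact to
its stage and SHA-256 checksum, so a rerun with the same config is
verifiably identical. An optional second feature table (e.g. inferred
pathway abundances) is pushed through the same ordination-to-analysis
machinery into a ``function/`` subtree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .analysis import AnalysisConfig, run_analysis
from .filtering import (
    FilterConfig,
    apply_sample_filters,
    assign_diet_specialists,
    restrict_to_specialists,
)
from .ordination import bray_curtis, pcoa, retain_axes, species_centroids

logger = logging.getLogger("paravec")


@dataclass
class PipelineConfig:
    """Paths and options for a full run; round-trips through JSON."""

    table: str
    metadata: str
    tree: str
    out_dir: str
    function_table: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_axis_prop: float = 0.001
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter"]["allowed_age_categories"] = sorted(
            self.filter.allowed_age_categories
        )
        d["filter"]["allowed_health_categories"] = sorted(
            self.filter.allowed_health_categories
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        f = dict(d.pop("filter", {}))
        for key in ("allowed_age_categories", "allowed_health_categories"):
            if key in f:
                f[key] = frozenset(f[key])
        a = dict(d.pop("analysis", {}))
        return cls(filter=FilterConfig(**f), analysis=AnalysisConfig(**a), **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyse_table(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    tree,
    diet_map: dict[str, str],
    config: PipelineConfig,
    out: Path,
    manifest: list[dict],
    stage_prefix: str = "",
) -> dict:
    """Ordination through analysis for one feature table; returns counts."""

    def emit(name: str, stage: str, writer) -> None:
        path = out / name
        writer(path)
        manifest.append(
            {"file": str(path.relative_to(out.parent if stage_prefix else out)),
             "stage": stage_prefix + stage, "sha256": _sha256(path)}
        )

    dm = bray_curtis(table)
    emit("distance_matrix.tsv", "ordinate", lambda p: pd.DataFrame(
        dm.data, index=dm.ids, columns=dm.ids).to_csv(p, sep="\t"))
    ordination = retain_axes(pcoa(dm), config.min_axis_prop)
    emit("eigenvalues.tsv", "ordinate", lambda p: pd.DataFrame(
        {"eigenvalue": ordination.eigenvalues,
         "proportion_explained": ordination.proportion_explained},
        index=ordination.coordinates.columns).to_csv(p, sep="\t", index_label="axis"))
    emit("coordinates.tsv", "ordinate",
         lambda p: ordination.coordinates.to_csv(p, sep="\t", index_label="sample_id"))

    centroids = species_centroids(ordination, metadata)
    emit("centroids.tsv", "ordinate", lambda p: centroids.coordinates.assign(
        n_samples=centroids.counts).to_csv(p, sep="\t", index_label="species"))

    report = run_analysis(centroids, diet_map, tree, config.analysis)

    vec_rows = []
    for _, r in report.contrasts.iterrows():
        vec_rows.append(r.to_dict())
    emit("vectors.tsv", "vectors", lambda p: pd.DataFrame(vec_rows).to_csv(
        p, sep="\t", index=False))
    emit("comparisons.tsv", "compare",
         lambda p: report.comparisons.to_csv(p, sep="\t", index=False))
    emit("quartets.tsv", "compare",
         lambda p: report.quartets.to_csv(p, sep="\t", index=False))
    emit("analysis_report.tsv", "analyze",
         lambda p: report.to_frame().to_csv(p, sep="\t", index=False))
    emit("analysis_report.md", "analyze",
         lambda p: p.write_text(report.to_markdown()))

    counts = {
        "n_retained_axes": ordination.n_axes,
        "n_species": len(centroids.species),
        "n_vectors": len(report.contrasts),
        "n_comparisons": len(report.comparisons),
        "comparisons_per_category": report.comparisons["category"]
        .value_counts().to_dict(),
        "n_quartets": len(report.quartets),
    }
    logger.info("%sordination/analysis done: %s", stage_prefix, counts)
    return counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def emit(name: str, stage: str, writer) -> None:
        path = out / name
        writer(path)
        manifest.append({"file": name, "stage": stage, "sha256": _sha256(path)})

    table = pio.read_feature_table(config.table)
    metadata = pio.read_metadata(config.metadata)
    tree = pio.read_tree(config.tree)

    ftable, fmeta, freport = apply_sample_filters(table, metadata, config.filter)
    diet_map = assign_diet_specialists(fmeta, config.filter.specialist_threshold)
    ftable, fmeta = restrict_to_specialists(ftable, fmeta, diet_map)
    logger.info(
        "filtering: %d -> %d samples; removals per rule: %s",
        freport.n_input_samples, len(fmeta), freport.counts(),
    )
    emit("filtered_table.tsv", "filter",
         lambda p: pio.write_feature_table(ftable, p))
    emit("filtered_metadata.tsv", "filter", lambda p: pio.write_metadata(fmeta, p))
    emit("filter_report.tsv", "filter",
         lambda p: freport.to_frame().to_csv(p, sep="\t", index=False))
    emit("diet_map.tsv", "filter", lambda p: pd.Series(diet_map, name="diet")
         .to_csv(p, sep="\t", index_label="species"))

    counts = _analyse_table(ftable, fmeta, tree, diet_map, config, out, manifest)

    if config.function_table is not None:
        ftab2 = pio.read_feature_table(config.function_table)
        ftab2 = ftab2.loc[:, fmeta["sample_id"].tolist()]
        fun_dir = out / "function"
        fun_dir.mkdir(exist_ok=True)
        counts_fun = _analyse_table(
            ftab2, fmeta, tree, diet_map, config, fun_dir, manifest,
            stage_prefix="function/",
        )
        counts = {"taxonomic": counts, "function": counts_fun}

    summary = {
        "config": config.to_dict(),
        "filter_removals": freport.counts(),
        "counts": counts,
        "artifacts": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
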