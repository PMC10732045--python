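"""End-to-end statistical report over a centroid set.

``run_analysis`` rebuilds the full comparison surface from species
centroids — all-pair vectors, categorized comparisons, quartets, diet
contrasts — and runs every test and trend fit, mirroring the order of a
(non)parallelism study's results: angle distributions by category,
parallel vs nonparallel trophic divergence, quartet comparison types,
length contrasts, and trends against host divergence time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .comparisons import (
    EXCLUDED,
    NONPARALLEL,
    PARALLEL,
    build_quartets,
    diet_contrast_groups,
    enumerate_comparisons,
)
from .ordination import CentroidSet
from .stats import compare_k_groups, compare_two_groups, fit_trend, normality_check
from .vectors import all_pair_vectors


@dataclass
class AnalysisConfig:
    """Options echoed into the report."""

    alpha: float = 0.05
    posthoc: str = "holm"
    equal_var: bool = False
    allow_shared_species: bool = False
    time_definition: str = "all-pairs"
    orientation: str = "global-order"
    min_group_size: int = 3
    seed: int = 0


@dataclass
class AnalysisReport:
    """Long-format report rows plus the per-comparison tables behind them."""

    rows: list[dict] = field(default_factory=list)
    comparisons: pd.DataFrame | None = None
    quartets: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    config: AnalysisConfig | None = None
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "section", "groups", "n", "statistic", "p", "adjusted_p",
            "variance_explained", "note",
        ]
        return pd.DataFrame(self.rows, columns=cols)

    def to_markdown(self) -> str:
        lines = ["# Analysis report", ""]
        frame = self.to_frame()
        for section, grp in frame.groupby("section", sort=False):
            lines.append(f"## {section}")
            lines.append("")
            for _, r in grp.iterrows():
                stat = "" if pd.isna(r["statistic"]) else f"stat={r['statistic']:.4g}, "
                p = "" if pd.isna(r["p"]) else f"p={r['p']:.3g}"
                ve = (
                    ""
                    if pd.isna(r["variance_explained"])
                    else f", R2={r['variance_explained']:.4g}"
                )
                note = f" ({r['note']})" if r["note"] else ""
                lines.append(f"- {r['groups']} [n={r['n']}]: {stat}{p}{ve}{note}")
            lines.append("")
        if self.skipped:
            lines.append("## Skipped")
            lines.append("")
            lines.extend(f"- {s}" for s in self.skipped)
            lines.append("")
        return "\n".join(lines)


def _row(section, groups, n, statistic=np.nan, p=np.nan, adjusted_p=np.nan,
         variance_explained=np.nan, note=""):
    return {
        "section": section, "groups": groups, "n": n, "statistic": statistic,
        "p": p, "adjusted_p": adjusted_p,
        "variance_explained": variance_explained, "note": note,
    }


def run_analysis(
    centroids: CentroidSet,
    diet_map: dict[str, str],
    tree: dendropy.Tree,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full statistical surface; deterministic given inputs."""
    config = config or AnalysisConfig()
    report = AnalysisReport(config=config)
    rows = report.rows

    vectors = all_pair_vectors(centroids, diet_map, "global-order")
    comparisons = enumerate_comparisons(
        vectors,
        tree,
        allow_shared_species=config.allow_shared_species,
        time_definition=config.time_definition,
        orientation=config.orientation,
    )
    report.comparisons = comparisons

    usable = comparisons.dropna(subset=["angle"])
    by_cat = {
        cat: grp["angle"].to_numpy()
        for cat, grp in usable.groupby("category")
        if cat != EXCLUDED
    }

    # 1. angle summaries per category, with normality gate
    for cat, angles in sorted(by_cat.items()):
        rows.append(_row("angles_by_category", f"{cat} mean", len(angles),
                         statistic=float(np.mean(angles)),
                         note=f"sd={np.std(angles, ddof=1):.4g}" if len(angles) > 1 else ""))
        if len(angles) >= 3 and np.ptp(angles) > 0:
            sw = normality_check(angles, seed=config.seed)
            rows.append(_row("angles_by_category", f"{cat} shapiro_wilk", len(angles),
                             statistic=sw.statistic, p=sw.pvalue, note=sw.note))

    # 2. parallel vs nonparallel trophic divergence: angles and times
    ok = all(
        cat in by_cat and len(by_cat[cat]) >= config.min_group_size
        for cat in (PARALLEL, NONPARALLEL)
    )
    if ok:
        par, non = by_cat[PARALLEL], by_cat[NONPARALLEL]
        t = compare_two_groups(par, non, method="t", equal_var=config.equal_var)
        w = compare_two_groups(par, non, method="wilcoxon")
        n = (len(par), len(non))
        rows.append(_row("parallel_vs_nonparallel_angles", "t-test", n,
                         statistic=t.statistic, p=t.pvalue))
        rows.append(_row("parallel_vs_nonparallel_angles", "wilcoxon", n,
                         statistic=w.statistic, p=w.pvalue))
        times = {
            cat: usable.loc[usable["category"] == cat, "mean_divergence_time"].to_numpy()
            for cat in (PARALLEL, NONPARALLEL)
        }
        tt = compare_two_groups(times[PARALLEL], times[NONPARALLEL], method="t",
                                equal_var=config.equal_var)
        rows.append(_row("parallel_vs_nonparallel_divergence_time", "t-test", n,
                         statistic=tt.statistic, p=tt.pvalue))
    else:
        report.skipped.append(
            "parallel_vs_nonparallel: a category has too few comparisons"
        )

    # 3. quartet comparison types
    quartets = build_quartets(centroids, diet_map, tree)
    report.quartets = quartets
    if len(quartets) >= config.min_group_size:
        groups = {
            "ecology_A1B1-A2B2": quartets["angle_ecology"].to_numpy(),
            "phylogeny_A1A2-B1B2": quartets["angle_phylogeny"].to_numpy(),
            "cross_A1B2-A2B1": quartets["angle_cross"].to_numpy(),
        }
        kg = compare_k_groups(groups, posthoc_correction=config.posthoc,
                              alpha=config.alpha)
        rows.append(_row("quartet_comparison_types", "kruskal_wallis",
                         tuple(len(v) for v in groups.values()),
                         statistic=kg.omnibus.statistic, p=kg.omnibus.pvalue))
        for _, pr in kg.pairwise.iterrows():
            rows.append(_row("quartet_comparison_types",
                             f"{pr['group1']} vs {pr['group2']}",
                             len(quartets), statistic=pr["statistic"],
                             p=pr["pvalue"], adjusted_p=pr["adjusted_p"]))
        for g, arr in groups.items():
            rows.append(_row("quartet_comparison_types", f"{g} mean", len(arr),
                             statistic=float(np.mean(arr)),
                             note=f"letters={kg.letters[g]}"))
    else:
        report.skipped.append("quartet_comparison_types: too few quartets")

    # 4. vector length by diet contrast
    contrasts = diet_contrast_groups(vectors, tree)
    report.contrasts = contrasts
    groups = {g: grp["length"].to_numpy() for g, grp in contrasts.groupby("group")}
    if all(len(groups.get(g, ())) >= config.min_group_size
           for g in ("same_diet", "different_diet")):
        w = compare_two_groups(groups["different_diet"], groups["same_diet"],
                               method="wilcoxon")
        n = (len(groups["different_diet"]), len(groups["same_diet"]))
        rows.append(_row("length_by_diet_contrast", "different vs same diet wilcoxon",
                         n, statistic=w.statistic, p=w.pvalue))
        for g in ("same_diet", "different_diet"):
            rows.append(_row("length_by_diet_contrast", f"{g} mean length",
                             len(groups[g]), statistic=float(np.mean(groups[g]))))
        tg = {g: contrasts.loc[contrasts["group"] == g, "divergence_time"].to_numpy()
              for g in ("same_diet", "different_diet")}
        wt = compare_two_groups(tg["different_diet"], tg["same_diet"], method="wilcoxon")
        rows.append(_row("length_by_diet_contrast",
                         "different vs same diet divergence time wilcoxon", n,
                         statistic=wt.statistic, p=wt.pvalue))
    else:
        report.skipped.append("length_by_diet_contrast: a group is too small")

    # 5. trends against divergence time
    def _trend(section, x, y):
        if len(x) < 10:
            report.skipped.append(f"{section}: fewer than 10 points")
            return
        fits = fit_trend(x, y)
        lin = fits["linear"]
        rows.append(_row(section, "linear", len(x), p=lin.pvalue,
                         variance_explained=lin.variance_explained))
        if fits["smooth"] is not None:
            sm = fits["smooth"]
            rows.append(_row(section, "smooth", len(x), p=sm.pvalue,
                             variance_explained=sm.variance_explained,
                             note=f"adj={sm.r_squared_adj:.4g}"))

    for cat, grp in usable.groupby("category"):
        if cat == EXCLUDED:
            continue
        _trend(f"angle_vs_divergence_time[{cat}]",
               grp["mean_divergence_time"].to_numpy(), grp["angle"].to_numpy())
    _trend("length_vs_divergence_time",
           contrasts["divergence_time"].to_numpy(), contrasts["length"].to_numpy())

    return report
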