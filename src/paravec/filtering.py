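"""Sample- and species-level filtering and the diet-specialist rule.

The filter sequence mirrors the study design for cross-species microbiota
comparisons: drop samples without an individual ID, deduplicate
individuals, keep only healthy adults, require a minimum sequencing depth,
require at least three individuals per species, cap each species at twenty
randomly chosen individuals, and finally keep only diet specialists
(species taking >= 70% of their diet from one category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoSamplesError, ValidationError
from .io import DIET_CATEGORIES, DIET_COLUMNS, validate_metadata

#: Filter rule names in application order.
RULE_ORDER = (
    "missing_individual_id",
    "duplicate_individual",
    "health_status",
    "age_category",
    "low_seq_count",
    "species_min_individuals",
    "species_subsample",
)


@dataclass
class FilterConfig:
    """Thresholds and allow-lists for :func:`apply_sample_filters`."""

    min_sequences: int = 1000
    min_individuals_per_species: int = 3
    max_individuals_per_species: int = 20
    allowed_age_categories: frozenset[str] = frozenset(
        {"adult", "after hatch year", "unknown"}
    )
    allowed_health_categories: frozenset[str] = frozenset({"healthy", "unknown"})
    specialist_threshold: float = 0.70
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.specialist_threshold <= 1:
            raise ValidationError("specialist_threshold must be in (0, 1]")
        if self.min_individuals_per_species > self.max_individuals_per_species:
            raise ValidationError("min individuals must not exceed max individuals")


@dataclass
class FilterReport:
    """Per-rule removals plus the surviving sample and species sets."""

    removed: dict[str, list[str]] = field(default_factory=dict)
    removed_species: dict[str, list[str]] = field(default_factory=dict)
    retained_samples: list[str] = field(default_factory=list)
    retained_species: list[str] = field(default_factory=list)
    subsample_seed: int = 0
    n_input_samples: int = 0

    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "n_removed": len(ids), "removed_ids": ";".join(ids)}
            for rule, ids in self.removed.items()
        ]
        return pd.DataFrame(rows, columns=["rule", "n_removed", "removed_ids"])


def _is_blank(value) -> bool:
    return pd.isna(value) or str(value).strip() == ""


def apply_sample_filters(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the ordered sample and species filters.

    Rules, in order: (1) drop samples without an individual ID; (2) keep
    one sample per individual (first by lexicographic sample ID); (3) keep
    allowed health statuses (blank counts as unknown); (4) keep allowed
    age categories (blank counts as unknown); (5) drop samples below the
    minimum sequence count; (6) drop species with fewer than the minimum
    number of remaining individuals; (7) subsample species above the
    maximum, uniformly at random under ``config.subsample_seed``.

    Returns the filtered table (columns restricted and ordered to the
    surviving samples), the filtered metadata, and a
    :class:`FilterReport` accounting for every removal.
    """
    config = config or FilterConfig()
    validate_metadata(metadata)
    unknown = set(metadata["sample_id"]) - set(table.columns)
    if unknown:
        raise ValidationError(f"metadata samples missing from table: {sorted(unknown)}")

    md = metadata.sort_values("sample_id", kind="stable").reset_index(drop=True)
    report = FilterReport(subsample_seed=config.subsample_seed, n_input_samples=len(md))

    def drop(rule: str, mask_drop: pd.Series) -> None:
        nonlocal md
        report.removed[rule] = md.loc[mask_drop, "sample_id"].tolist()
        md = md.loc[~mask_drop].reset_index(drop=True)

    drop("missing_individual_id", md["individual_id"].map(_is_blank))
    drop("duplicate_individual", md.duplicated(subset="individual_id", keep="first"))
    health = md["health"].map(lambda v: "unknown" if _is_blank(v) else str(v).lower())
    drop("health_status", ~health.isin(config.allowed_health_categories))
    age = md["age_category"].map(lambda v: "unknown" if _is_blank(v) else str(v).lower())
    drop("age_category", ~age.isin(config.allowed_age_categories))
    drop("low_seq_count", md["seq_count"].astype(float) < config.min_sequences)

    sizes = md.groupby("species")["individual_id"].nunique()
    small = sizes[sizes < config.min_individuals_per_species].index
    report.removed_species["species_min_individuals"] = sorted(small)
    drop("species_min_individuals", md["species"].isin(small))

    rng = np.random.default_rng(config.subsample_seed)
    dropped_sub: list[str] = []
    for sp in sorted(md["species"].unique()):
        ids = sorted(md.loc[md["species"] == sp, "sample_id"])
        if len(ids) > config.max_individuals_per_species:
            keep = rng.choice(ids, size=config.max_individuals_per_species, replace=False)
            dropped_sub.extend(sorted(set(ids) - set(keep)))
    drop("species_subsample", md["sample_id"].isin(dropped_sub))

    if md.empty:
        raise NoSamplesError("no samples survive the filters")

    report.retained_samples = md["sample_id"].tolist()
    report.retained_species = sorted(md["species"].unique())
    filtered_table = table.loc[:, report.retained_samples]
    return filtered_table, md, report


def assign_diet_specialists(
    metadata: pd.DataFrame, specialist_threshold: float = 0.70
) -> dict[str, str]:
    """Map each diet-specialist species to its diet category.

    A specialist consumes ``specialist_threshold`` (default 70%) or more of
    one diet category; the threshold is inclusive. Non-specialists are
    simply absent from the returned map. Diet fractions must be constant
    across a species' samples (within 1e-6); a conflict is an error.
    """
    if not 0 < specialist_threshold <= 1:
        raise ValidationError("specialist_threshold must be in (0, 1]")
    out: dict[str, str] = {}
    for sp, grp in metadata.groupby("species"):
        fracs = grp[list(DIET_COLUMNS)].astype(float)
        spread = fracs.max(axis=0) - fracs.min(axis=0)
        if (spread > 1e-6).any():
            bad = spread[spread > 1e-6].index.tolist()
            raise ValidationError(
                f"diet fractions for species {sp!r} disagree across samples: {bad}"
            )
        mean = fracs.iloc[0]
        if mean.max() >= specialist_threshold:
            out[str(sp)] = DIET_CATEGORIES[int(np.argmax(mean.to_numpy()))]
    return out


def restrict_to_specialists(
    table: pd.DataFrame, metadata: pd.DataFrame, diet_map: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subset a table/metadata pair to species present in ``diet_map``."""
    md = metadata[metadata["species"].isin(diet_map)].reset_index(drop=True)
    if md.empty:
        raise NoSamplesError("no specialist species remain")
    return table.loc[:, md["sample_id"].tolist()], md
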