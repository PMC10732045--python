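"""Reading and writing of feature tables, sample metadata, and host trees.

Feature tables are plain TSV with features as rows and samples as columns;
the first column holds feature IDs. Metadata is a per-sample TSV keyed by
``sample_id``. Trees are Newick with branch lengths in millions of years.
"""

from __future__ import annotations

import os

import dendropy
import pandas as pd

from .errors import FormatError, ValidationError

#: The six host diet categories used for the specialist classification.
DIET_CATEGORIES = (
    "fruits",
    "invertebrates",
    "meat-endotherms",
    "meat-fish",
    "plants",
    "seeds",
)

#: Metadata columns holding per-category diet fractions.
DIET_COLUMNS = tuple("diet_" + c.replace("-", "_") for c in DIET_CATEGORIES)

#: Required metadata columns, in canonical order.
METADATA_COLUMNS = (
    "sample_id",
    "individual_id",
    "species",
    "age_category",
    "health",
    "captive_wild",
    "seq_count",
) + DIET_COLUMNS


def diet_column(category: str) -> str:
    """Metadata column name for a diet category."""
    if category not in DIET_CATEGORIES:
        raise ValidationError(f"unknown diet category: {category!r}")
    return "diet_" + category.replace("-", "_")


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check ID uniqueness and non-negativity of a feature table."""
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature IDs: {dups}")
    if table.columns.duplicated().any():
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs: {dups}")
    if (table.to_numpy() < 0).any():
        raise ValidationError("feature table contains negative abundances")
    return table


def read_feature_table(path: str | os.PathLike, format_hint: str = "tsv") -> pd.DataFrame:
    """Read a features x samples abundance table.

    Parameters
    ----------
    path
        Path to a TSV file whose first column holds feature IDs and whose
        remaining columns are samples.
    format_hint
        Only ``"tsv"`` is supported; a BIOM hint raises a format error.

    Returns
    -------
    pandas.DataFrame
        Features as the index, samples as columns.
    """
    if format_hint.lower() != "tsv":
        raise FormatError(
            f"unsupported feature-table format {format_hint!r}; "
            "provide a features x samples TSV"
        )
    try:
        # mangle_dupe_cols was removed from pandas; detect duplicate sample
        # columns from the raw header instead.
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        table = pd.read_csv(path, sep="\t", index_col=0)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse feature table {path}: {exc}") from exc
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"duplicate sample IDs: {dups}")
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return validate_feature_table(table)


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_feature_table(table)
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-sample metadata TSV and validate its columns."""
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise FormatError(f"metadata is missing columns: {missing}")
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
    return validate_metadata(md)


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    fracs = md[list(DIET_COLUMNS)].astype(float)
    if (fracs.to_numpy() < 0).any() or (fracs.to_numpy() > 1).any():
        raise ValidationError("diet fractions must lie in [0, 1]")
    if (fracs.sum(axis=1) > 1 + 1e-6).any():
        bad = md.loc[fracs.sum(axis=1) > 1 + 1e-6, "sample_id"].tolist()
        raise ValidationError(f"diet fractions sum to more than 1 for samples {bad}")
    if (md["seq_count"].astype(float) < 0).any():
        raise ValidationError("seq_count must be non-negative")
    return md


def write_metadata(md: pd.DataFrame, path: str | os.PathLike) -> None:
    md.to_csv(path, sep="\t", index=False)


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths in myr."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse Newick tree {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError("tree tip labels are not unique")
    return tree


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
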