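"""Input parsing, validation and clinical filtering.

Reads an FPKM-scale expression matrix (genes x samples), a gene catalog
(biotype plus immune-gene membership) and a clinical table, applies the
cohort-level record filters, and partitions genes into the lncRNA and
immune protein-coding universes used by the screening stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

MIN_FOLLOWUP_DAYS = 31  # records with follow-up below this are dropped


class ValidationError(ValueError):
    """Raised when an input violates the pipeline's contracts."""


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample abundance table with tumor/normal labels.

    ``values`` is a genes-by-samples DataFrame on the FPKM scale;
    ``groups`` maps every sample to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene IDs in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample IDs in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression values")
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValidationError(f"samples without a group label: {list(missing)[:5]}")
        self.groups = self.groups.reindex(self.values.columns)
        bad = set(self.groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.groups)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.groups.loc[samples])

    def tumor_samples(self) -> pd.Index:
        return self.sample_ids[self.groups.to_numpy() == TUMOR]

    def normal_samples(self) -> pd.Index:
        return self.sample_ids[self.groups.to_numpy() == NORMAL]


@dataclass
class GeneCatalog:
    """gene_id -> biotype plus an immune-gene flag.

    The immune flag marks membership in an immune-gene list and is only
    meaningful for protein-coding genes.
    """

    table: pd.DataFrame  # index gene_id; columns: biotype, immune

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate gene IDs in catalog")
        bad = self.table.loc[self.table["immune"] & (self.table["biotype"] != "protein_coding")]
        if len(bad):
            raise ValidationError(
                f"immune flag set on non-protein-coding genes: {list(bad.index)[:5]}"
            )

    def lncrna_genes(self) -> pd.Index:
        return self.table.index[self.table["biotype"] == "lncRNA"]

    def immune_genes(self) -> pd.Index:
        return self.table.index[self.table["immune"]]


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path, group_map) -> ExpressionMatrix:
    """Parse a delimited expression table and attach group labels.

    First column holds gene IDs, the header holds sample IDs.  Duplicate
    gene rows are collapsed by their arithmetic mean on the FPKM scale.
    ``group_map`` may be a dict or Series mapping sample -> tumor/normal.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df = df.apply(pd.to_numeric)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"negative expression values in {path}")
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    groups = pd.Series(dict(group_map) if not isinstance(group_map, pd.Series) else group_map)
    missing = df.columns.difference(groups.index)
    if len(missing):
        raise ValidationError(f"samples missing from group map: {list(missing)[:5]}")
    return ExpressionMatrix(df, groups.reindex(df.columns))


def read_gene_catalog(biotype_path, immune_list_path) -> GeneCatalog:
    """Read a two-column (gene_id, biotype) table and a one-column immune list."""
    bt = pd.read_csv(biotype_path, sep=_sep_for(biotype_path))
    bt = bt.set_index(bt.columns[0])
    bt.columns = ["biotype"]
    with open(immune_list_path) as fh:
        immune = {line.strip() for line in fh if line.strip()}
    bt["immune"] = [(g in immune) and (b == "protein_coding") for g, b in bt["biotype"].items()]
    # membership of a non-coding gene in the immune list is ignored, not fatal
    return GeneCatalog(bt)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table (sample, futime_days, fustat, age, stage, T, M, N)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    df = df.rename(columns={df.columns[0]: "sample"})
    required = {"sample", "futime", "fustat"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    return df


def filter_clinical(clinical: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Apply the cohort record filters.

    Drops records with follow-up time fewer than 31 days (futime >= 31
    retained) and reduces duplicated sample IDs to their first occurrence.
    Returns (filtered table, n retained, n dropped).  Idempotent.
    """
    n0 = len(clinical)
    out = clinical.loc[clinical["futime"] >= MIN_FOLLOWUP_DAYS]
    out = out.loc[~out["sample"].duplicated(keep="first")].reset_index(drop=True)
    if not (out["fustat"].isin([0, 1])).all():
        raise ValidationError("fustat must be binary")
    if len(out) == 0:
        raise ValidationError("no clinical records remain after filtering")
    return out, len(out), n0 - len(out)


def partition_genes(
    expr: ExpressionMatrix, catalog: GeneCatalog
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split the expression matrix into lncRNA and immune-mRNA submatrices.

    Genes absent from the catalog are excluded with a warning; the two
    outputs are disjoint by construction (a gene is either lncRNA or
    immune-flagged protein-coding, never both).
    """
    known = expr.gene_ids.intersection(catalog.table.index)
    unknown = expr.gene_ids.difference(catalog.table.index)
    if len(unknown):
        warnings.warn(f"{len(unknown)} genes absent from catalog were excluded")
    lnc = [g for g in known if catalog.table.at[g, "biotype"] == "lncRNA"]
    imm = [g for g in known if catalog.table.at[g, "immune"]]
    return expr.subset_genes(lnc), expr.subset_genes(imm)
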