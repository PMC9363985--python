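"""Core in-memory containers for heterokaryon expression analysis.

The central object is :class:`CountMatrix`, a thin wrapper around a
gene x sample integer DataFrame plus per-sample library sizes and
normalization factors (the same bookkeeping edgeR's DGEList carries).
Sample metadata travels as a validated :class:`SampleSheet`; allele-resolved
counts (reads uniquely assigned to the mat A or mat a nucleus) as
:class:`AlleleCounts` in long format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("vegetative", "sexual")
KARYOTYPES = ("homoA", "homoa", "het")

SAMPLE_COLUMNS = (
    "sample_id",
    "lineage",
    "stage",
    "karyotype",
    "initial_ratio",
    "dna_ratio",
    "replicate",
)


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts with library bookkeeping.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.
    lib_sizes
        Per-sample library size; defaults to column sums.
    norm_factors
        Per-sample normalization factors (TMM-style); default 1.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series | None = None
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.rename_axis(index="gene_id", columns=None)
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise SchemaError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id: {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, index=self.counts.columns, dtype=float)
            if (self.lib_sizes <= 0).any():
                raise SchemaError("library sizes must be positive")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        else:
            self.norm_factors = pd.Series(
                self.norm_factors, index=self.counts.columns, dtype=float
            )
            if (self.norm_factors <= 0).any():
                raise SchemaError("normalization factors must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(gene_ids)],
            lib_sizes=self.lib_sizes,
            norm_factors=self.norm_factors,
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        keep = list(sample_ids)
        return CountMatrix(
            self.counts[keep],
            lib_sizes=self.lib_sizes[keep],
            norm_factors=self.norm_factors[keep],
        )

    def with_factors(self, factors: pd.Series) -> "CountMatrix":
        return CountMatrix(self.counts, lib_sizes=self.lib_sizes, norm_factors=factors)


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet; returns the frame indexed by sample_id."""
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample id: {dup!r}")
    bad_stage = ~df["stage"].isin(STAGES)
    if bad_stage.any():
        row = df.loc[bad_stage].iloc[0]
        raise SchemaError(
            f"unknown stage {row['stage']!r} for sample {row['sample_id']!r}"
        )
    bad_k = ~df["karyotype"].isin(KARYOTYPES)
    if bad_k.any():
        row = df.loc[bad_k].iloc[0]
        raise SchemaError(
            f"unknown karyotype {row['karyotype']!r} for sample {row['sample_id']!r}"
        )
    for col in ("initial_ratio", "dna_ratio"):
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.isna() | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            row = df.loc[~ok].iloc[0]
            raise SchemaError(
                f"{col} outside [0,1] for sample {row['sample_id']!r}"
            )
    return df.set_index("sample_id", drop=False)


def validate_allele_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate long-format allele counts (gene_id, sample_id, matA, mata)."""
    need = ["gene_id", "sample_id", "matA_count", "mata_count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"allele counts missing columns: {missing}")
    if df.duplicated(["gene_id", "sample_id"]).any():
        row = df.loc[df.duplicated(["gene_id", "sample_id"])].iloc[0]
        raise SchemaError(
            f"duplicate (gene, sample) pair: ({row['gene_id']!r}, {row['sample_id']!r})"
        )
    for col in ("matA_count", "mata_count"):
        if (df[col] < 0).any():
            row = df.loc[df[col] < 0].iloc[0]
            raise SchemaError(f"negative {col} for gene {row['gene_id']!r}")
    return df.reset_index(drop=True)


def validate_orthologs(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an orthologue table (cluster_id, strain, gene_id)."""
    need = ["cluster_id", "strain", "gene_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"ortholog table missing columns: {missing}")
    if df.duplicated(["cluster_id", "strain"]).any():
        row = df.loc[df.duplicated(["cluster_id", "strain"])].iloc[0]
        raise SchemaError(
            f"cluster {row['cluster_id']!r} has multiple genes for strain {row['strain']!r}"
        )
    return df.reset_index(drop=True)
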