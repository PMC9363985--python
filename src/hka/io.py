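"""TSV readers and writers for the count / sample / allele / ortholog schemas.

All files are UTF-8, tab-separated, '.' decimal. Schemas:

* ``counts.tsv``        — gene_id + one integer column per sample
* ``samples.tsv``       — sample_id, lineage, stage, karyotype, initial_ratio,
                          dna_ratio, replicate
* ``allele_counts.tsv`` — gene_id, sample_id, matA_count, mata_count
* ``orthologs.tsv``     — cluster_id, strain, gene_id
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    SchemaError,
    validate_allele_counts,
    validate_orthologs,
    validate_samples,
)


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[vals.isna()][0]
            raise SchemaError(f"{path}: non-numeric count for gene {gene!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            gene = df.index[~np.isclose(vals, np.round(vals))][0]
            raise SchemaError(f"{path}: non-integer count for gene {gene!r}, sample {col!r}")
    return CountMatrix(df.astype(np.int64))


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_allele_counts(df)


def write_allele_counts(ac: pd.DataFrame, path) -> None:
    ac.to_csv(path, sep="\t", index=False)


def read_orthologs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_orthologs(df)


def write_orthologs(orthologs: pd.DataFrame, path) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
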