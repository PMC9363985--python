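"""Library-size normalization: low-expression filtering, trimmed mean of
M-values (TMM) factors, and orthologue-anchored cross-strain normalization.

TMM follows the canonical definition: per non-reference library, gene-wise
log2 expression ratios M against the reference and average log abundances A
are doubly trimmed (30% of each M tail, 5% of each A tail) and the surviving
M values averaged with inverse asymptotic-variance weights; factors are then
rescaled to geometric mean 1. The reference library is the one whose
upper-quartile expression is closest to the mean upper quartile.

Cross-strain comparisons cannot use gene-wise factors directly because each
strain has its own gene set; instead, factors are computed on a joint matrix
restricted to orthologue clusters shared by every strain and attached back to
each library's full count matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, SchemaError


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     n_obs: float | None = None, n_ref: float | None = None,
                     logratio_trim: float = 0.3, sum_trim: float = 0.05,
                     weighted: bool = True) -> float:
    """TMM factor of one library against the reference library.

    ``n_obs`` / ``n_ref`` are the library sizes; they default to the column
    sums but may be larger (orthologue-restricted matrices keep the full
    library size)."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    n_obs = obs.sum() if n_obs is None else float(n_obs)
    n_ref = ref.sum() if n_ref is None else float(n_ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[fin], abs_e[fin], var[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    ``ref_sample`` overrides the automatic upper-quartile reference choice.
    Raises on degenerate input (fewer than 2 samples, or an all-zero library).
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = cm.sample_ids[counts.sum(axis=0) == 0][0]
        raise ValueError(f"library {bad!r} has no counts; cannot normalize")
    if ref_sample is None:
        f75 = np.quantile(counts, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(cm.sample_ids.get_loc(ref_sample))
    ref = counts[:, ref_idx]
    factors = np.array([
        _tmm_pair_factor(counts[:, j], ref, lib[j], lib[ref_idx],
                         logratio_trim, sum_trim)
        for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="norm_factor")


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million on the effective library size (lib_size x factor)."""
    eff = cm.effective_lib_sizes().to_numpy()
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return cm.counts / eff * 1e6


def filter_low_expression(cm: CountMatrix, min_cpm: float = 1.0,
                          min_samples: int = 3) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_samples samples.

    Gene order is preserved; library sizes are kept from the full matrix.
    """
    if min_cpm < 0:
        raise ValueError("min_cpm must be >= 0")
    if min_cpm == 0:
        return cm
    keep = (cpm(cm) >= min_cpm).sum(axis=1) >= min_samples
    return cm.subset_genes(cm.gene_ids[keep])


def orthologue_normalize(cms: dict[str, CountMatrix],
                         orthologs: pd.DataFrame) -> dict[str, CountMatrix]:
    """Cross-strain normalization anchored on shared orthologue clusters.

    ``cms`` maps strain name -> that strain's CountMatrix; ``orthologs`` has
    columns (cluster_id, strain, gene_id). TMM factors are computed on the
    joint cluster x sample matrix restricted to clusters shared by all
    strains, then attached to each strain's full matrix. Library sizes stay
    the full-matrix column sums.
    """
    strains = list(cms)
    missing = set(strains) - set(orthologs["strain"].unique())
    if missing:
        raise ValueError(f"strains absent from ortholog table: {sorted(missing)}")
    sub = orthologs[orthologs["strain"].isin(strains)]
    per_cluster = sub.groupby("cluster_id")["strain"].nunique()
    shared = per_cluster.index[per_cluster == len(strains)]
    if len(shared) == 0:
        raise ValueError("no orthologue clusters shared by all strains")

    blocks = []
    for strain in strains:
        genes = (sub[sub["strain"] == strain]
                 .set_index("cluster_id")["gene_id"]
                 .reindex(shared))
        present = genes.dropna()
        present = present[present.isin(cms[strain].gene_ids)]
        block = (cms[strain].counts.reindex(present.to_numpy())
                 .set_axis(present.index, axis=0)
                 .reindex(shared, fill_value=0))
        blocks.append(block)
    joint = pd.concat(blocks, axis=1)
    # library sizes stay each library's FULL column sum so that a genuine
    # expression shift on the shared orthologues is seen as such, not as a
    # depth change
    full_lib = pd.concat([cms[s].lib_sizes for s in strains])
    joint_cm = CountMatrix(joint.fillna(0).astype(np.int64),
                           lib_sizes=full_lib[joint.columns])
    factors = tmm_factors(joint_cm)

    out = {}
    for strain in strains:
        f = factors[cms[strain].sample_ids]
        out[strain] = cms[strain].with_factors(f)
    return out


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style TMM normalizer.

    ``fit`` computes per-library factors; ``transform`` returns CPM on the
    effective library size. Accepts a CountMatrix or a genes x samples
    DataFrame of raw counts.

    Attributes
    ----------
    norm_factors_ : pd.Series
        TMM factors, geometric mean 1.
    lib_sizes_ : pd.Series
        Library sizes used (column sums unless the CountMatrix overrides).
    """

    def __init__(self, ref_sample: str | None = None,
                 logratio_trim: float = 0.3, sum_trim: float = 0.05):
        self.ref_sample = ref_sample
        self.logratio_trim = logratio_trim
        self.sum_trim = sum_trim

    @staticmethod
    def _as_cm(X) -> CountMatrix:
        if isinstance(X, CountMatrix):
            return X
        return CountMatrix(pd.DataFrame(X))

    def fit(self, X, y=None):
        cm = self._as_cm(X)
        self.norm_factors_ = tmm_factors(
            cm, ref_sample=self.ref_sample,
            logratio_trim=self.logratio_trim, sum_trim=self.sum_trim,
        )
        self.lib_sizes_ = cm.lib_sizes.copy()
        return self

    def transform(self, X) -> pd.DataFrame:
        cm = self._as_cm(X)
        return cpm(cm.with_factors(self.norm_factors_[cm.sample_ids]))
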