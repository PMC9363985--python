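"""Negative-binomial differential expression between sample groups.

The model: counts y_gj ~ NB(mu_gj, phi_g) with log mu_gj = beta_g,k(j) +
log(effective library size_j), i.e. a one-way log-linear layout with the
effective library size as offset. Group means are fitted per gene by
Newton iterations on the log scale (vectorized across genes) and contrasts
are tested with likelihood-ratio chi-squared statistics.

Dispersions phi_g are method-of-moments estimates from within-group
residuals on the effective-library-size scale, shrunk toward a fitted
mean-dispersion trend with a fixed prior weight (edgeR-style prior
degrees of freedom). This is a deliberately simplified stand-in for
quasi-likelihood machinery: calibration is established by simulation in
the test suite rather than by matching any external tool's internals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

DISPERSION_FLOOR = 1e-6


def _as_group_series(cm: CountMatrix, groups) -> pd.Series:
    g = pd.Series(groups)
    if not g.index.equals(cm.sample_ids):
        if len(g) != cm.n_samples:
            raise ValueError("groups length does not match number of samples")
        g.index = cm.sample_ids
    return g.astype(str)


def _nb_ll_kernel(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood, dropping terms that depend on (y, phi)
    only — those cancel in likelihood ratios at fixed dispersion."""
    phi = phi[:, None]
    mu = np.maximum(mu, 1e-300)
    t1 = np.where(y > 0, y * np.log(phi * mu / (1.0 + phi * mu)), 0.0)
    t2 = -np.log1p(phi * mu) / phi
    return (t1 + t2).sum(axis=1)


def _fit_offset_scale(y: np.ndarray, s: np.ndarray, phi: np.ndarray,
                      base: np.ndarray | None = None, n_iter: int = 25,
                      tol: float = 1e-10):
    """MLE of a common scale exp(beta) for mu_j = exp(beta) * base_j.

    ``base`` defaults to the offsets ``s`` (plain group-mean fit). Returns
    (mu, ll) with mu shaped genes x samples. Vectorized Newton on beta.
    """
    if base is None:
        base = np.broadcast_to(s, y.shape)
    base = np.maximum(base, 1e-12)
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / base.sum(axis=1))
    phi_c = phi[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * base
        w = 1.0 + phi_c * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(beta)[:, None] * base
    # genes with zero total: mean is exactly zero
    zero = tot == 0
    if zero.any():
        mu[zero] = 0.0
    return mu, _nb_ll_kernel(y, mu, phi)


def _fit_groupwise(y, s, phi, labels: np.ndarray, uniq) -> tuple[np.ndarray, np.ndarray]:
    """Fit separate means per group; returns (mu, ll)."""
    mu = np.zeros_like(y, dtype=float)
    for lab in uniq:
        idx = np.where(labels == lab)[0]
        m, _ = _fit_offset_scale(y[:, idx], s[idx], phi)
        mu[:, idx] = m
    return mu, _nb_ll_kernel(y, mu, phi)


def estimate_dispersions(cm: CountMatrix, groups, prior_df: float = 10.0,
                         n_bins: int = 20) -> pd.Series:
    """Per-gene NB dispersion by moments, shrunk toward an abundance trend.

    Within each group with >= 2 replicates, the group mean on the effective
    library-size scale gives fitted mu; the moment identity
    Var = mu + phi*mu^2 yields a per-gene raw phi. Raw values are shrunk
    toward the binned-trend value with weight prior_df / (prior_df + df),
    where df is the total residual degrees of freedom, and floored at 1e-6.
    """
    g = _as_group_series(cm, groups)
    y = cm.counts.to_numpy(dtype=float)
    s = cm.effective_lib_sizes().to_numpy()
    counts_per_group = g.value_counts()
    replicated = counts_per_group.index[counts_per_group >= 2]
    if len(replicated) == 0:
        raise ValueError(
            "no group has replicates; supply a common dispersion instead")

    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    df = 0
    for lab in replicated:
        idx = np.where(g.to_numpy() == lab)[0]
        n_k = len(idx)
        q = y[:, idx].sum(axis=1) / s[idx].sum()
        mu = q[:, None] * s[idx]
        resid2 = (y[:, idx] - mu) ** 2 * (n_k / (n_k - 1))
        num += (resid2 - mu).sum(axis=1)
        den += (mu ** 2).sum(axis=1)
        df += n_k - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    raw = np.clip(raw, 0.0, 100.0)

    # abundance trend: mean raw dispersion in quantile bins of log mean CPM
    mean_cpm = (y / s * 1e6).mean(axis=1)
    order = np.argsort(mean_cpm)
    expressed = den > 0
    trend = np.full(y.shape[0], np.nan)
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = np.minimum((ranks * n_bins) // max(len(order), 1), n_bins - 1)
    bin_means = {}
    for b in range(n_bins):
        sel = (bins == b) & expressed
        if sel.any():
            bin_means[b] = raw[sel].mean()
    fallback = raw[expressed].mean() if expressed.any() else 0.0
    for b in range(n_bins):
        v = bin_means.get(b, fallback)
        trend[bins == b] = v

    w = prior_df / (prior_df + max(df, 1))
    phi = (1.0 - w) * raw + w * trend
    phi = np.maximum(phi, DISPERSION_FLOOR)
    return pd.Series(phi, index=cm.gene_ids, name="dispersion")


def nb_lrt(cm: CountMatrix, groups, dispersions: pd.Series,
           sample_ids=None) -> pd.DataFrame:
    """Analysis-of-deviance LRT of equal means across all group labels."""
    g = _as_group_series(cm, groups)
    if sample_ids is not None:
        cm = cm.subset_samples(sample_ids)
        g = g[cm.sample_ids]
    y = cm.counts.to_numpy(dtype=float)
    s = cm.effective_lib_sizes().to_numpy()
    phi = dispersions.reindex(cm.gene_ids).to_numpy()
    labels = g.to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    _, ll_null = _fit_offset_scale(y, s, phi)
    _, ll_alt = _fit_groupwise(y, s, phi, labels, uniq)
    lr = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lr, df=len(uniq) - 1)
    return pd.DataFrame({"gene_id": cm.gene_ids, "statistic": lr,
                         "p_value": p}).set_index("gene_id", drop=False)


def nb_test(cm: CountMatrix, groups, contrast: tuple[str, str],
            dispersions: pd.Series | None = None,
            prior_cpm: float = 0.5) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test.

    ``contrast = (group1, group2)``; log2_fc is group2 over group1, computed
    from normalized group means with a ``prior_cpm`` pseudo-abundance.
    Returns one row per gene with p_value and BH fdr.
    """
    g = _as_group_series(cm, groups)
    g1, g2 = contrast
    for lab in contrast:
        if lab not in set(g):
            raise ValueError(f"unknown contrast group {lab!r}")
    keep = g.isin([g1, g2])
    sub = cm.subset_samples(cm.sample_ids[keep])
    gsub = g[keep]
    if dispersions is None:
        dispersions = estimate_dispersions(sub, gsub)
    res = nb_lrt(sub, gsub, dispersions)

    y = sub.counts.to_numpy(dtype=float)
    s = sub.effective_lib_sizes().to_numpy()
    m = {}
    for lab in contrast:
        idx = (gsub == lab).to_numpy()
        m[lab] = y[:, idx].sum(axis=1) / s[idx].sum() * 1e6
    log2_fc = np.log2((m[g2] + prior_cpm) / (m[g1] + prior_cpm))

    out = pd.DataFrame({
        "gene_id": sub.gene_ids,
        "log2_fc": log2_fc,
        "p_value": res["p_value"].to_numpy(),
        f"mean_cpm_{g1}": m[g1],
        f"mean_cpm_{g2}": m[g2],
        "dispersion": dispersions.reindex(sub.gene_ids).to_numpy(),
    }).set_index("gene_id", drop=False)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def conservation_test(cm: CountMatrix, groups, alpha: float = 0.05,
                      dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Call genes conserved vs non-conserved across all composition groups.

    A gene is conserved iff the across-group analysis of deviance is
    non-significant at BH FDR ``alpha``.
    """
    g = _as_group_series(cm, groups)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, g)
    res = nb_lrt(cm, g, dispersions)
    fdr = multipletests(res["p_value"], method="fdr_bh")[1]
    return pd.DataFrame({
        "gene_id": res["gene_id"],
        "p_value": res["p_value"],
        "fdr": fdr,
        "call": np.where(fdr < alpha, "non_conserved", "conserved"),
    }).set_index("gene_id", drop=False)


def nb_offset_test(cm: CountMatrix, expectations: pd.DataFrame,
                   dispersions: pd.Series) -> pd.DataFrame:
    """Test observed counts against fixed per-sample expected counts.

    Null: mu_gj = E_gj (the expectation, already on the counts scale).
    Alternative: mu_gj = exp(beta_g) * E_gj. One-degree LRT per gene; used
    for the additivity test where E is the nuclear-ratio-weighted mixture
    of homokaryon means.
    """
    E = expectations.reindex(index=cm.gene_ids, columns=cm.sample_ids)
    y = cm.counts.to_numpy(dtype=float)
    base = np.maximum(E.to_numpy(dtype=float), 1e-8)
    phi = dispersions.reindex(cm.gene_ids).to_numpy()
    mu0 = base
    ll0 = _nb_ll_kernel(y, mu0, phi)
    _, ll1 = _fit_offset_scale(y, cm.effective_lib_sizes().to_numpy(), phi,
                               base=base)
    lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(lr, df=1)
    return pd.DataFrame({"gene_id": cm.gene_ids, "statistic": lr,
                         "p_value": p}).set_index("gene_id", drop=False)


class NBTest(BaseEstimator):
    """Estimator wrapper: fit dispersions once, test many contrasts.

    Parameters
    ----------
    alpha : float
        FDR level used by :meth:`conservation`.
    prior_df : float
        Prior degrees of freedom for dispersion shrinkage.

    Attributes
    ----------
    dispersions_ : pd.Series
        Trend-shrunken per-gene NB dispersions.
    groups_ : pd.Series
        Sample -> group labels seen in fit.
    """

    def __init__(self, alpha: float = 0.05, prior_df: float = 10.0):
        self.alpha = alpha
        self.prior_df = prior_df

    def fit(self, X: CountMatrix, y=None):
        if y is None:
            raise ValueError("group labels are required")
        self.cm_ = X
        self.groups_ = _as_group_series(X, y)
        self.dispersions_ = estimate_dispersions(X, self.groups_,
                                                 prior_df=self.prior_df)
        return self

    def test(self, contrast: tuple[str, str]) -> pd.DataFrame:
        return nb_test(self.cm_, self.groups_, contrast,
                       dispersions=self.dispersions_)

    def conservation(self) -> pd.DataFrame:
        return conservation_test(self.cm_, self.groups_, alpha=self.alpha,
                                 dispersions=self.dispersions_)

    def offset_test(self, expectations: pd.DataFrame,
                    sample_ids=None) -> pd.DataFrame:
        cm = self.cm_ if sample_ids is None else self.cm_.subset_samples(sample_ids)
        return nb_offset_test(cm, expectations, self.dispersions_)
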