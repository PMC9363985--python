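"""Allele-ratio regression: nucleus-specific expression vs nuclear ratio.

For every gene the mat A expression ratio R (fraction of allele-assignable
reads from mat A nuclei) is regressed on the nuclear DNA ratio D by ordinary
least squares, R = beta0 + beta1 * D, one fit per gene. Under independent
nuclear expression the line is the identity (slope 1, intercept 0);
departures flag heterokaryon-level co-regulation such as dosage
compensation.

Upstream mapping-quality filters use homokaryon samples, where the true
allele origin is known: genes with > 5% reads assigned to the absent
nucleus, or whose homokaryon-based regression slope CI excludes 1, are
removed as mapping artefacts. Stage contrasts use gene-level Z-scores
(sexual-stage centering, vegetative-stage scaling) and a Mann-Whitney test
on the two slope distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_MIN_TOTAL = 10


def allele_ratio(ac: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL) -> pd.DataFrame:
    """Per (gene, sample) mat A expression ratio matA/(matA+mata).

    Pairs with fewer than ``min_total`` assignable reads are missing (NaN).
    Returns a genes x samples DataFrame.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    total = ac["matA_count"] + ac["mata_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total >= min_total, ac["matA_count"] / total, np.nan)
    long = ac[["gene_id", "sample_id"]].assign(ratio=ratio)
    return long.pivot(index="gene_id", columns="sample_id", values="ratio")


def mismap_filter(homokaryon_ac: pd.DataFrame, samples: pd.DataFrame,
                  threshold: float = 0.05,
                  min_total: int = DEFAULT_MIN_TOTAL) -> pd.Index:
    """Genes whose worst-case homokaryon mismapping is <= threshold.

    ``homokaryon_ac`` must contain homokaryon samples only (reads assigned
    to the nucleus absent from a homokaryon are mismapped by definition).
    The per-gene mismap rate is maximized over homokaryon samples with at
    least ``min_total`` assignable reads; genes with no such sample (no
    uniquely mapped reads) are dropped.
    """
    meta = samples.set_index("sample_id")
    karyo = meta.loc[homokaryon_ac["sample_id"], "karyotype"].to_numpy()
    if (karyo == "het").any():
        bad = homokaryon_ac["sample_id"].to_numpy()[karyo == "het"][0]
        raise ValueError(f"heterokaryon sample {bad!r} passed to mismap_filter")
    wrong = np.where(karyo == "homoA",
                     homokaryon_ac["mata_count"], homokaryon_ac["matA_count"])
    total = (homokaryon_ac["matA_count"] + homokaryon_ac["mata_count"]).to_numpy()
    ok = total >= min_total
    frac = pd.DataFrame({
        "gene_id": homokaryon_ac["gene_id"].to_numpy()[ok],
        "mismap": wrong[ok] / total[ok],
    })
    if len(frac) == 0:
        return pd.Index([], name="gene_id")
    worst = frac.groupby("gene_id")["mismap"].max()
    return worst.index[worst <= threshold]


def _ols_lines(D: np.ndarray, R: np.ndarray, ci_level: float):
    """Vectorized per-row OLS of R (genes x samples, NaN = missing) on D."""
    valid = np.isfinite(R)
    x = np.where(valid, D, 0.0)
    y = np.where(valid, R, 0.0)
    n = valid.sum(axis=1).astype(float)
    sx = x.sum(axis=1)
    sy = y.sum(axis=1)
    sxx = (x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    syy = (y * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = sxx - sx * sx / n
        estimable = (n >= 3) & (ssx > 1e-12)
        slope = (sxy - sx * sy / n) / ssx
        intercept = (sy - slope * sx) / n
        ss_res = syy - sy * sy / n - slope * slope * ssx
        ss_res = np.maximum(ss_res, 0.0)
        sigma2 = ss_res / (n - 2.0)
        se_slope = np.sqrt(sigma2 / ssx)
        se_int = np.sqrt(sigma2 * (1.0 / n + (sx / n) ** 2 / ssx))
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, np.maximum(n - 2.0, 1.0))
    out = {
        "slope": np.where(estimable, slope, np.nan),
        "intercept": np.where(estimable, intercept, np.nan),
        "se_slope": np.where(estimable, se_slope, np.nan),
        "se_intercept": np.where(estimable, se_int, np.nan),
        "n_points": n.astype(int),
        "estimable": estimable,
    }
    out["ci_slope_lo"] = out["slope"] - tcrit * out["se_slope"]
    out["ci_slope_hi"] = out["slope"] + tcrit * out["se_slope"]
    out["ci_intercept_lo"] = out["intercept"] - tcrit * out["se_intercept"]
    out["ci_intercept_hi"] = out["intercept"] + tcrit * out["se_intercept"]
    return out


def ratio_regression(ratios: pd.DataFrame, dna_ratio: pd.Series,
                     ci_level: float = 0.95) -> pd.DataFrame:
    """Per-gene OLS of expression ratio on DNA ratio with t-based CIs.

    ``ratios`` is genes x samples (NaN = missing); ``dna_ratio`` gives D per
    sample. Genes with < 3 informative points or constant D are flagged
    unestimable rather than raising.
    """
    D = dna_ratio.reindex(ratios.columns).to_numpy(dtype=float)
    res = _ols_lines(D, ratios.to_numpy(dtype=float), ci_level)
    out = pd.DataFrame(res, index=ratios.index)
    out.insert(0, "gene_id", ratios.index)
    return out


def gene_ratio_regression(points, ci_level: float = 0.95) -> pd.Series:
    """OLS line through a list of (D, R) points for a single gene."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (D, R) pairs")
    ratios = pd.DataFrame([pts[:, 1]], index=pd.Index(["gene"], name="gene_id"),
                          columns=range(len(pts)))
    dna = pd.Series(pts[:, 0], index=range(len(pts)))
    return ratio_regression(ratios, dna, ci_level=ci_level).iloc[0]


def homokaryon_slope_filter(regressions: pd.DataFrame) -> pd.Index:
    """Keep genes whose homokaryon-based slope CI contains 1.

    Homokaryon samples have known D in {0, 1}; a slope away from 1 there can
    only come from mapping artefacts. Unestimable genes are dropped.
    """
    ok = regressions["estimable"] & \
        (regressions["ci_slope_lo"] <= 1.0) & (regressions["ci_slope_hi"] >= 1.0)
    return regressions.index[ok.fillna(False)]


def flag_coregulation(regressions: pd.DataFrame) -> pd.DataFrame:
    """Flag slope CIs excluding 1 and intercept CIs excluding 0.

    Adds boolean ``slope_ne_1`` / ``intercept_ne_0`` and direction columns
    ("above"/"below"/""). Unestimable genes carry no flags.
    """
    out = regressions.copy()
    est = out["estimable"].fillna(False).astype(bool)
    lo1, hi1 = out["ci_slope_lo"], out["ci_slope_hi"]
    lo0, hi0 = out["ci_intercept_lo"], out["ci_intercept_hi"]
    out["slope_ne_1"] = est & ((hi1 < 1.0) | (lo1 > 1.0))
    out["slope_direction"] = np.select(
        [est & (hi1 < 1.0), est & (lo1 > 1.0)], ["below", "above"], default="")
    out["intercept_ne_0"] = est & ((hi0 < 0.0) | (lo0 > 0.0))
    out["intercept_direction"] = np.select(
        [est & (hi0 < 0.0), est & (lo0 > 0.0)], ["below", "above"], default="")
    return out


def stage_zscores(sexual_regs: pd.DataFrame,
                  vegetative_regs: pd.DataFrame,
                  center: str = "sexual_mean") -> pd.DataFrame:
    """Gene-level Z-scores contrasting sexual against vegetative fits.

    Default (``center="sexual_mean"``) follows the verbatim construction:
    z_slope(g) = (slope_sexual(g) - mean(slope_sexual)) / sd(slope_vegetative),
    and analogously for intercepts; |z| > 2 marks significance. The
    alternative ``center="vegetative_gene"`` centers each gene on its own
    vegetative estimate instead.
    """
    shared = sexual_regs.index.intersection(vegetative_regs.index)
    sex = sexual_regs.loc[shared]
    veg = vegetative_regs.loc[shared]
    est = (sex["estimable"] & veg["estimable"]).to_numpy(dtype=bool)
    if est.sum() < 3:
        raise ValueError("need >= 3 genes with estimable fits in both stages")
    out = pd.DataFrame(index=shared)
    out["gene_id"] = shared
    for par in ("slope", "intercept"):
        sd_veg = veg.loc[est, par].std(ddof=1)
        if sd_veg == 0 or not np.isfinite(sd_veg):
            raise ValueError(f"vegetative {par} SD is zero; Z-scores undefined")
        if center == "sexual_mean":
            ref = sex.loc[est, par].mean()
            z = (sex[par] - ref) / sd_veg
        elif center == "vegetative_gene":
            z = (sex[par] - veg[par]) / sd_veg
        else:
            raise ValueError(f"unknown centering {center!r}")
        out[f"z_{par}"] = np.where(est, z, np.nan)
    out["z_slope_significant"] = np.abs(out["z_slope"]) > 2
    out["z_intercept_significant"] = np.abs(out["z_intercept"]) > 2
    return out


def compare_slope_distributions(slopes_a, slopes_b):
    """Mann-Whitney U test between two slope collections.

    Exact null distribution for small samples (both n <= 20, no ties),
    normal approximation with tie correction otherwise. Returns
    (U statistic, two-sided p).
    """
    a = np.asarray(pd.Series(slopes_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(slopes_b).dropna(), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both slope lists must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


class RatioRegression(BaseEstimator, RegressorMixin):
    """Per-gene OLS of expression ratio on DNA ratio, sklearn-style.

    ``fit(X, y)`` takes X = DNA ratios (one per sample) and y = genes x
    samples expression-ratio DataFrame; fitted lines land in ``results_``
    with co-regulation flags.

    Attributes
    ----------
    results_ : pd.DataFrame
        slope/intercept, CIs, flags per gene.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, X, y):
        dna = pd.Series(np.asarray(X, dtype=float), index=y.columns)
        reg = ratio_regression(y, dna, ci_level=self.ci_level)
        self.results_ = flag_coregulation(reg)
        return self

    def predict(self, X) -> pd.DataFrame:
        """Predicted expression ratio at the given DNA ratios."""
        d = np.asarray(X, dtype=float)
        r = self.results_
        return pd.DataFrame(
            r["intercept"].to_numpy()[:, None] + np.outer(r["slope"], d),
            index=r.index)


def ase_pipeline(ac: pd.DataFrame, samples: pd.DataFrame,
                 mismap_threshold: float = 0.05,
                 min_total: int = DEFAULT_MIN_TOTAL,
                 ci_level: float = 0.95) -> dict:
    """Full allele-specific analysis for one lineage's samples.

    Order: homokaryon mismap filter -> homokaryon slope filter -> per-stage
    heterokaryon regressions on the shared kept-gene set -> co-regulation
    flags, stage Z-scores, and the between-stage Mann-Whitney slope test.
    Heterokaryon D is the measured DNA ratio; homokaryons contribute D in
    {0, 1} to the filter regressions only.
    """
    meta = samples.set_index("sample_id")
    is_homo = meta["karyotype"].isin(["homoA", "homoa"])
    homo_ids = meta.index[is_homo]
    ac_homo = ac[ac["sample_id"].isin(homo_ids)]

    kept = mismap_filter(ac_homo, samples, threshold=mismap_threshold,
                         min_total=min_total)

    ratios = allele_ratio(ac, min_total=min_total)
    homo_d = meta.loc[homo_ids, "karyotype"].map({"homoA": 1.0, "homoa": 0.0})
    homo_cols = [s for s in ratios.columns if s in set(homo_ids)]
    homo_reg = ratio_regression(ratios.loc[kept, homo_cols],
                                homo_d[homo_cols], ci_level=ci_level)
    kept = homokaryon_slope_filter(homo_reg)

    per_stage = {}
    for stage in ("vegetative", "sexual"):
        ids = meta.index[(meta["karyotype"] == "het") & (meta["stage"] == stage)]
        cols = [s for s in ratios.columns if s in set(ids)]
        if not cols:
            continue
        reg = ratio_regression(ratios.loc[kept, cols],
                               meta.loc[cols, "dna_ratio"], ci_level=ci_level)
        per_stage[stage] = flag_coregulation(reg)

    out = {"kept_genes": kept, "homokaryon_regressions": homo_reg,
           "regressions": per_stage}
    if {"vegetative", "sexual"} <= set(per_stage):
        sex, veg = per_stage["sexual"], per_stage["vegetative"]
        out["zscores"] = stage_zscores(sex, veg)
        est = sex["estimable"] & veg["estimable"]
        u, p = compare_slope_distributions(sex.loc[est, "slope"],
                                           veg.loc[est, "slope"])
        out["mann_whitney"] = {
            "U": u, "p_value": p,
            "median_slope_sexual": float(sex.loc[est, "slope"].median()),
            "median_slope_vegetative": float(veg.loc[est, "slope"].median()),
        }
    return out
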