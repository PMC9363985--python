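"""Classification of heterokaryon expression modes relative to homokaryons.

For each gene expressed in the vegetative stage, total heterokaryon
expression is compared with the two homokaryons while accounting for the
realized nuclear ratio. The decision tree:

1. conserved — no difference across the five nuclear compositions
   (homoA, homoa, het90, het50, het10);
2. other_difference — non-conserved but homokaryons do not differ;
3. additive — homokaryons differ and no heterokaryon group deviates from
   the nuclear-ratio-weighted expectation E = r*mu_A + (1-r)*mu_a;
4. dominant_A / dominant_a — deviates from additivity, indistinguishable
   from one homokaryon and distinguishable from the other;
5. over_dominant / under_dominant — significantly above / below both
   homokaryons (transgressive);
6. intermediate — deviates from additivity but fits no template.

Each level is tested with BH FDR within the genes reaching that level,
mirroring the nested percentages of the summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .diffexpr import NBTest, nb_offset_test

MODES = ("conserved", "additive", "dominant_A", "dominant_a",
         "over_dominant", "under_dominant", "intermediate", "other_difference")


def additive_expectation(mu_A, mu_a, r):
    """Expected heterokaryon expression under nuclear-ratio additivity:
    E = r*mu_A + (1-r)*mu_a."""
    mu_A = np.asarray(mu_A, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("nuclear ratio outside [0,1]")
    if np.any(mu_A < 0) or np.any(mu_a < 0):
        raise ValueError("expression means must be >= 0")
    return r * mu_A + (1.0 - r) * mu_a


def composition_labels(samples: pd.DataFrame) -> pd.Series:
    """Nuclear-composition group per sample: homoA / homoa / het<percent>."""
    lab = samples["karyotype"].copy()
    het = lab == "het"
    lab[het] = [
        f"het{int(round(r * 100))}" for r in samples.loc[het, "initial_ratio"]
    ]
    lab.index = samples["sample_id"]
    return lab


def _bh_significant(p: pd.Series, alpha: float) -> pd.Series:
    if len(p) == 0:
        return pd.Series(dtype=bool)
    return pd.Series(multipletests(p, method="fdr_bh")[1] < alpha, index=p.index)


def classify_modes(cm: CountMatrix, samples: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene expression-mode calls on vegetative samples.

    ``samples`` must carry measured DNA ratios for every heterokaryon
    sample; there is no silent fallback to the inoculum label.
    Returns one row per gene with the mode and the supporting p-values.
    """
    veg = samples[samples["stage"] == "vegetative"]
    if len(veg) == 0:
        raise ValueError("no vegetative samples")
    groups = composition_labels(veg)
    need = {"homoA", "homoa"}
    het_groups = sorted(set(groups) - need)
    if not need <= set(groups) or len(het_groups) == 0:
        raise ValueError(
            f"need homoA, homoa and heterokaryon groups; got {sorted(set(groups))}")
    het_ids = list(veg.loc[veg["karyotype"] == "het", "sample_id"])
    dna = veg.set_index("sample_id")["dna_ratio"]
    missing = dna[het_ids].isna()
    if missing.any():
        bad = missing.index[missing][0]
        raise ValueError(f"missing measured DNA ratio for heterokaryon sample {bad!r}")

    sub = cm.subset_samples(groups.index)
    engine = NBTest(alpha=alpha).fit(sub, groups)

    # level 1: conservation across all five compositions
    cons = engine.conservation()
    conserved = cons["call"] == "conserved"

    calls = pd.DataFrame(index=sub.gene_ids)
    calls["gene_id"] = sub.gene_ids
    calls["mode"] = "conserved"
    calls["p_conservation"] = cons["p_value"]

    noncons = sub.gene_ids[~conserved]
    if len(noncons):
        # level 2: do the homokaryons differ?
        mat = engine.test(("homoa", "homoA"))
        p_mat = mat.loc[noncons, "p_value"]
        mat_sig = _bh_significant(p_mat, alpha)
        calls.loc[noncons, "p_mat"] = p_mat
        other = noncons[~mat_sig.to_numpy()]
        calls.loc[other, "mode"] = "other_difference"
        differing = noncons[mat_sig.to_numpy()]
    else:
        differing = sub.gene_ids[:0]

    if len(differing):
        y = sub.counts
        s = sub.effective_lib_sizes()
        q = {}
        for lab in ("homoA", "homoa"):
            ids = groups.index[groups == lab]
            q[lab] = y[ids].sum(axis=1) / s[ids].sum()

        # level 3: per-heterokaryon-group additivity (expectation as offset)
        deviates = pd.Series(False, index=differing)
        for lab in het_groups:
            ids = groups.index[groups == lab]
            d = dna[ids]
            expect = pd.DataFrame(
                {sid: additive_expectation(q["homoA"], q["homoa"], d[sid]) * s[sid]
                 for sid in ids}, index=sub.gene_ids)
            grp_cm = sub.subset_samples(ids).subset_genes(differing)
            res = nb_offset_test(grp_cm, expect.loc[differing],
                                 engine.dispersions_)
            sig = _bh_significant(res["p_value"], alpha)
            calls.loc[differing, f"p_additive_{lab}"] = res["p_value"]
            deviates |= sig
        additive = differing[~deviates.to_numpy()]
        calls.loc[additive, "mode"] = "additive"
        nonadd = differing[deviates.to_numpy()]
    else:
        nonadd = sub.gene_ids[:0]

    if len(nonadd):
        # levels 4-5: dominance / transgressivity templates; the three
        # heterokaryon ratio groups are pooled since dominance predicts one
        # common mean at every ratio
        het_pool = groups.copy()
        het_pool[het_pool.isin(het_groups)] = "het"
        pool_engine = NBTest(alpha=alpha)
        pool_engine.cm_ = sub
        pool_engine.groups_ = het_pool
        pool_engine.dispersions_ = engine.dispersions_
        vs_A = pool_engine.test(("homoA", "het")).loc[nonadd]
        vs_a = pool_engine.test(("homoa", "het")).loc[nonadd]
        sig_A = _bh_significant(vs_A["p_value"], alpha)
        sig_a = _bh_significant(vs_a["p_value"], alpha)
        calls.loc[nonadd, "p_vs_homoA"] = vs_A["p_value"]
        calls.loc[nonadd, "p_vs_homoa"] = vs_a["p_value"]

        het_cpm = vs_A["mean_cpm_het"]
        cpm_A = vs_A["mean_cpm_homoA"]
        cpm_a = vs_a["mean_cpm_homoa"]
        above = (het_cpm > cpm_A) & (het_cpm > cpm_a)
        below = (het_cpm < cpm_A) & (het_cpm < cpm_a)

        mode = pd.Series("intermediate", index=nonadd)
        mode[~sig_A & sig_a] = "dominant_A"
        mode[sig_A & ~sig_a] = "dominant_a"
        mode[sig_A & sig_a & above] = "over_dominant"
        mode[sig_A & sig_a & below] = "under_dominant"
        calls.loc[nonadd, "mode"] = mode

    return calls


def summarize_modes(calls: pd.DataFrame) -> pd.DataFrame:
    """Nested count/percentage summary (percentages are of the group one
    nesting level higher)."""
    if len(calls) == 0:
        raise ValueError("no mode calls to summarize")
    mode = calls["mode"]
    total = len(mode)
    n_cons = int((mode == "conserved").sum())
    n_noncons = total - n_cons
    n_other = int((mode == "other_difference").sum())
    n_diff = n_noncons - n_other
    n_add = int((mode == "additive").sum())
    n_nonadd = n_diff - n_add

    def pct(n, d):
        return 100.0 * n / d if d else np.nan

    rows = [
        ("total_expressed", total, 100.0),
        ("conserved", n_cons, pct(n_cons, total)),
        ("non_conserved", n_noncons, pct(n_noncons, total)),
        ("mat_differing", n_diff, pct(n_diff, n_noncons)),
        ("additive", n_add, pct(n_add, n_diff)),
        ("non_additive", n_nonadd, pct(n_nonadd, n_diff)),
        ("other_difference", n_other, pct(n_other, n_noncons)),
    ]
    for m in ("dominant_A", "dominant_a", "over_dominant", "under_dominant",
              "intermediate"):
        n = int((mode == m).sum())
        rows.append((m, n, pct(n, n_nonadd)))
    return pd.DataFrame(rows, columns=["category", "n_genes", "percent"])


class ModeClassifier(BaseEstimator):
    """Estimator interface over :func:`classify_modes`.

    Attributes
    ----------
    calls_ : pd.DataFrame
        Per-gene mode calls with supporting p-values.
    summary_ : pd.DataFrame
        Nested count/percentage table.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: CountMatrix, y: pd.DataFrame):
        self.calls_ = classify_modes(X, y, alpha=self.alpha)
        self.summary_ = summarize_modes(self.calls_)
        return self

    def predict(self, X=None) -> pd.Series:
        return self.calls_["mode"]
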