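"""Mating-type-biased vs stage-biased gene overlap (2x2 chi-squared).

Bias calls follow the explicit selection rule |log2 fold change| > 1 and
raw p < 0.05 (no FDR here — the rule is stated on raw p), computed on
homokaryon samples only: mat bias contrasts the two homokaryons within a
stage; stage bias contrasts the two stages within homokaryons. The overlap
table rows are {vegetative-biased, sexual-biased} and columns
{mat a-biased, mat A-biased}; association is tested by Pearson chi-squared
with Yates continuity correction (R's default for 2x2 tables, which
reproduces the study's printed p-values).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def biased_genes(de: pd.DataFrame, lfc_threshold: float = 1.0,
                 p_threshold: float = 0.05) -> dict[str, pd.Index]:
    """Split DE results into up-/down-biased gene sets.

    ``de`` is an nb_test result table (log2_fc of group2 over group1).
    Returns {"up": genes with log2_fc > threshold, "down": ...}, both
    requiring raw p < p_threshold.
    """
    sig = de["p_value"] < p_threshold
    up = de.index[sig & (de["log2_fc"] > lfc_threshold)]
    down = de.index[sig & (de["log2_fc"] < -lfc_threshold)]
    return {"up": up, "down": down}


def build_bias_table(mat_sets: dict[str, pd.Index],
                     stage_sets: dict[str, pd.Index]) -> pd.DataFrame:
    """2x2 intersection counts of direction-labelled bias sets.

    ``mat_sets`` keys: "mat_a" / "mat_A"; ``stage_sets`` keys:
    "vegetative" / "sexual". Each cell is the number of genes biased both
    ways; a gene cannot be biased in both directions of one axis.
    """
    table = pd.DataFrame(
        [[len(set(stage_sets["vegetative"]) & set(mat_sets["mat_a"])),
          len(set(stage_sets["vegetative"]) & set(mat_sets["mat_A"]))],
         [len(set(stage_sets["sexual"]) & set(mat_sets["mat_a"])),
          len(set(stage_sets["sexual"]) & set(mat_sets["mat_A"]))]],
        index=["vegetative_biased", "sexual_biased"],
        columns=["mat_a_biased", "mat_A_biased"],
    )
    return table


def overlap_chisq(table, correction: bool = True):
    """Chi-squared test of the 2x2 bias-overlap table.

    Yates continuity correction is on by default (matches R's chisq.test
    for 2x2 tables). Returns (chi2, p); a zero row or column margin makes
    the test undefined and returns (nan, nan).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        # a zero margin (including an empty table) leaves the expected
        # counts undefined; report missing rather than raise
        return float("nan"), float("nan")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


def bias_overlap_analysis(de_mat: pd.DataFrame, de_stage: pd.DataFrame,
                          lfc_threshold: float = 1.0,
                          p_threshold: float = 0.05,
                          correction: bool = True) -> dict:
    """Bias sets, the 2x2 table and its chi-squared test in one call.

    ``de_mat``: homokaryon mat a vs mat A contrast (log2_fc > 0 = higher in
    mat A homokaryon). ``de_stage``: vegetative vs sexual contrast
    (log2_fc > 0 = higher in sexual stage).
    """
    mat = biased_genes(de_mat, lfc_threshold, p_threshold)
    stage = biased_genes(de_stage, lfc_threshold, p_threshold)
    mat_sets = {"mat_A": mat["up"], "mat_a": mat["down"]}
    stage_sets = {"sexual": stage["up"], "vegetative": stage["down"]}
    table = build_bias_table(mat_sets, stage_sets)
    chi2, p = overlap_chisq(table, correction=correction)
    return {"mat_sets": mat_sets, "stage_sets": stage_sets,
            "table": table, "chi2": chi2, "p_value": p}
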