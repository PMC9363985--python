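"""Synthetic heterokaryon RNA-seq experiments with known ground truth.

Emulates the design of the *N. tetrasperma* study: per lineage, two
developmental stages (vegetative, sexual) and five nuclear compositions —
two homokaryons (pure mat A, pure mat a) and heterokaryons inoculated at
90% / 50% / 10% mat A — with three biological replicates each
(30 samples per lineage).

The generative model, per gene g and sample s:

* totals are negative binomial with mean ``libsize_s * q_gs / 1e6`` where
  ``q_gs`` is the expected expression in CPM units and per-gene dispersion
  is drawn lognormal;
* heterokaryon expected expression is the nuclear-ratio-weighted mixture
  ``r*mu_A + (1-r)*mu_a`` unless the gene carries a dominant or
  transgressive mode effect;
* reads distinguishable between the two nuclei are a binomial split of
  ``round(assignable_fraction * total)`` with mat A probability
  ``clip(beta0 + beta1*r, 0, 1)``, contaminated by symmetric mismapping;
* realized nuclear ratios drift from the inoculum on the logit scale, and
  the sample sheet carries a noisy qPCR-like "measured" DNA ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import CountMatrix
from . import io as hio

MODE_LABELS = ("conserved", "additive", "dominant_A", "dominant_a",
               "over_dominant", "under_dominant")


@dataclass
class DriftParams:
    """Logit-scale drift of realized nuclear ratio from the inoculum."""

    bias: float = 0.0
    sd: float = 0.3


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_replicates: int = 3
    lineages: tuple = ("L1", "L6", "L10")
    stages: tuple = ("vegetative", "sexual")
    initial_ratios: tuple = (0.9, 0.5, 0.1)
    # log2-CPM baseline expression distribution
    mean_log_expression: float = 5.0
    sd_log_expression: float = 2.0
    # lognormal per-gene NB dispersion: ln(phi) ~ N(log(0.05), 0.5^2)
    dispersion_log_mean: float = float(np.log(0.05))
    dispersion_log_sd: float = 0.5
    library_size_mean: float = 5e6
    library_size_log_sd: float = 0.15
    # homokaryon mat A / mat a expression differences
    frac_mat_biased: float = 0.2
    mat_bias_log2fc: float = 2.0
    frac_stage_biased: float = 0.3
    stage_bias_log2fc: float = 2.0
    # heterokaryon expression-mode mixture; remainder of the gene set is
    # conserved (or additive when the gene is mat-biased)
    mode_mix: dict = field(default_factory=lambda: {
        "dominant_A": 0.01, "dominant_a": 0.01,
        "over_dominant": 0.005, "under_dominant": 0.005,
    })
    transgressive_log2fc: float = 1.0
    # per-stage allele-ratio programs R = beta0 + beta1 * D
    slope_by_stage: dict = field(default_factory=lambda: {
        "vegetative": (1.0, 0.0), "sexual": (0.6, 0.1),
    })
    intercept_by_stage: dict = field(default_factory=lambda: {
        "vegetative": (0.0, 0.0), "sexual": (0.2, 0.05),
    })
    assignable_fraction: float = 0.8
    # per-gene mismap rate ~ Beta(a, b); mean ~0.03 so a tail crosses the
    # 5% homokaryon filtering threshold
    mismap_beta: tuple = (1.0, 30.0)
    ratio_drift: DriftParams = field(default_factory=DriftParams)
    measured_ratio_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for r in self.initial_ratios:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"initial ratio {r} outside [0,1]")
        for frac in (self.frac_mat_biased, self.frac_stage_biased,
                     self.assignable_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0,1]")
        bad = set(self.mode_mix) - set(MODE_LABELS)
        if bad:
            raise ValueError(f"unknown mode labels in mode_mix: {sorted(bad)}")
        if sum(self.mode_mix.values()) > 1.0 + 1e-12:
            raise ValueError("mode_mix fractions must sum to <= 1")
        if min(self.mode_mix.values(), default=0.0) < 0.0:
            raise ValueError("mode_mix fractions must be >= 0")
        # allele programs for stages not simulated are harmless; stages
        # without a program fall back to the identity line (1, 0)


@dataclass
class SimulationTruth:
    """Ground truth: per-gene programs and per-sample realized ratios."""

    genes: pd.DataFrame       # mode, mu_A/mu_a per stage, beta0/beta1, mismap
    sample_ratios: pd.Series  # realized mat A nuclear fraction per sample


def simulate_nuclear_ratios(initial_ratio, drift: DriftParams, n: int,
                            rng=None) -> np.ndarray:
    """Realized nuclear ratios for ``n`` replicate tissues from one inoculum.

    Ratios drift on the logit scale: logit(r) ~ N(logit(initial) + bias, sd^2).
    Homokaryon inocula (0 or 1) are fixed points and returned unchanged; with
    zero drift the initial ratio is returned exactly.
    """
    if not 0.0 <= initial_ratio <= 1.0:
        raise ValueError(f"initial ratio {initial_ratio} outside [0,1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if initial_ratio in (0.0, 1.0):
        return np.full(n, float(initial_ratio))
    if drift.bias == 0.0 and drift.sd == 0.0:
        return np.full(n, float(initial_ratio))
    rng = np.random.default_rng() if rng is None else rng
    z = logit(initial_ratio) + drift.bias + drift.sd * rng.standard_normal(n)
    return expit(z)


def _draw_modes(cfg: SimulationConfig, rng) -> np.ndarray:
    labels = list(cfg.mode_mix.keys())
    probs = np.array([cfg.mode_mix[k] for k in labels])
    u = rng.random(cfg.n_genes)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    mode = np.full(cfg.n_genes, "conserved", dtype=object)
    for i, lab in enumerate(labels):
        mode[(u >= edges[i]) & (u < edges[i + 1])] = lab
    return mode


def simulate_experiment(cfg: SimulationConfig):
    """Simulate the full design; returns (CountMatrix, AlleleCounts,
    SampleSheet, SimulationTruth). Deterministic for a fixed config seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(G)], name="gene_id")

    # --- per-gene programs -------------------------------------------------
    base_log2 = rng.normal(cfg.mean_log_expression, cfg.sd_log_expression, G)
    base_cpm = 2.0 ** base_log2
    phi = rng.lognormal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, G)
    mismap = rng.beta(*cfg.mismap_beta, G)

    mode = _draw_modes(cfg, rng)
    mat_biased = rng.random(G) < cfg.frac_mat_biased
    # dominant / transgressive modes only make sense with a mat difference
    mat_biased |= mode != "conserved"
    mat_sign = rng.choice([-1.0, 1.0], G)
    mat_lfc = np.where(mat_biased, mat_sign * cfg.mat_bias_log2fc, 0.0)
    # effective truth label: mat-biased additive genes are "additive"
    eff_mode = mode.copy()
    eff_mode[(mode == "conserved") & mat_biased] = "additive"

    stage_biased = rng.random(G) < cfg.frac_stage_biased
    stage_sign = rng.choice([-1.0, 1.0], G)
    stage_lfc = np.where(stage_biased, stage_sign * cfg.stage_bias_log2fc, 0.0)

    # homokaryon means in CPM units (geometric split of the mat difference)
    mu_A = base_cpm * 2.0 ** (mat_lfc / 2.0)
    mu_a = base_cpm * 2.0 ** (-mat_lfc / 2.0)

    beta = {}
    for st in cfg.stages:
        b1m, b1s = cfg.slope_by_stage.get(st, (1.0, 0.0))
        b0m, b0s = cfg.intercept_by_stage.get(st, (0.0, 0.0))
        beta[st] = (rng.normal(b1m, b1s, G), rng.normal(b0m, b0s, G))

    # --- samples -----------------------------------------------------------
    rows = []
    true_r = {}
    for lin in cfg.lineages:
        for st in cfg.stages:
            comps = [("homoA", 1.0), ("homoa", 0.0)] + [
                (f"het{int(round(r * 100))}", r) for r in cfg.initial_ratios
            ]
            for comp, init in comps:
                karyo = comp if comp in ("homoA", "homoa") else "het"
                rs = simulate_nuclear_ratios(init, cfg.ratio_drift,
                                             cfg.n_replicates, rng)
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{lin}_{st[:3]}_{comp}_r{rep}"
                    r = rs[rep - 1]
                    if karyo == "het":
                        meas = float(expit(logit(r) + cfg.measured_ratio_sd
                                           * rng.standard_normal()))
                    else:
                        meas = r
                    rows.append({
                        "sample_id": sid, "lineage": lin, "stage": st,
                        "karyotype": karyo, "initial_ratio": init,
                        "dna_ratio": meas, "replicate": rep,
                        "true_ratio": r,
                    })
                    true_r[sid] = r
    samples = pd.DataFrame(rows)
    S = len(samples)
    sample_ids = samples["sample_id"].to_numpy()

    # --- expected expression (CPM units), genes x samples ------------------
    lib = rng.lognormal(np.log(cfg.library_size_mean), cfg.library_size_log_sd, S)
    q = np.empty((G, S))
    for j in range(S):
        st = samples["stage"].iloc[j]
        r = samples["true_ratio"].iloc[j]
        smul = 2.0 ** (stage_lfc * (1.0 if st == "sexual" else 0.0))
        a, b = mu_A * smul, mu_a * smul
        if samples["karyotype"].iloc[j] == "homoA":
            q[:, j] = a
        elif samples["karyotype"].iloc[j] == "homoa":
            q[:, j] = b
        else:
            e = r * a + (1.0 - r) * b
            e = np.where(eff_mode == "dominant_A", a, e)
            e = np.where(eff_mode == "dominant_a", b, e)
            hi, lo = np.maximum(a, b), np.minimum(a, b)
            e = np.where(eff_mode == "over_dominant",
                         hi * 2.0 ** cfg.transgressive_log2fc, e)
            e = np.where(eff_mode == "under_dominant",
                         lo * 2.0 ** -cfg.transgressive_log2fc, e)
            q[:, j] = e

    mu = q * (lib / 1e6)
    n_nb = 1.0 / phi
    counts = rng.negative_binomial(n_nb[:, None], (n_nb / (n_nb + mu.T)).T)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))

    # --- allele split ------------------------------------------------------
    assignable = np.rint(cfg.assignable_fraction * counts).astype(np.int64)
    p_true = np.empty((G, S))
    for j in range(S):
        karyo = samples["karyotype"].iloc[j]
        if karyo in ("homoA", "homoa"):
            p_true[:, j] = 1.0 if karyo == "homoA" else 0.0
        else:
            b1, b0 = beta[samples["stage"].iloc[j]]
            p_true[:, j] = np.clip(b0 + b1 * samples["true_ratio"].iloc[j], 0.0, 1.0)
    p_obs = p_true * (1.0 - mismap[:, None]) + (1.0 - p_true) * mismap[:, None]
    matA = rng.binomial(assignable, p_obs)
    ac = pd.DataFrame({
        "gene_id": np.repeat(gene_ids.to_numpy(), S),
        "sample_id": np.tile(sample_ids, G),
        "matA_count": matA.ravel(),
        "mata_count": (assignable - matA).ravel(),
    })

    truth_genes = pd.DataFrame({"gene_id": gene_ids, "mode": eff_mode,
                                "mat_log2fc": mat_lfc, "stage_log2fc": stage_lfc,
                                "mu_A": mu_A, "mu_a": mu_a,
                                "dispersion": phi, "mismap_rate": mismap})
    for st in cfg.stages:
        truth_genes[f"beta1_{st}"] = beta[st][0]
        truth_genes[f"beta0_{st}"] = beta[st][1]
    truth = SimulationTruth(
        genes=truth_genes.set_index("gene_id", drop=False),
        sample_ratios=pd.Series(true_r, name="true_ratio"),
    )
    return cm, ac, samples, truth


def write_fixture(outputs, directory) -> dict:
    """Write a simulated experiment as the four TSV files; returns the paths."""
    cm, ac, samples, truth = outputs
    d = hio.ensure_dir(directory)
    paths = {
        "counts": d / "counts.tsv",
        "allele_counts": d / "allele_counts.tsv",
        "samples": d / "samples.tsv",
        "truth": d / "truth.tsv",
    }
    hio.write_counts(cm, paths["counts"])
    hio.write_allele_counts(ac, paths["allele_counts"])
    hio.write_samples(samples, paths["samples"])
    truth.genes.reset_index(drop=True).to_csv(paths["truth"], sep="\t", index=False)
    return paths
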