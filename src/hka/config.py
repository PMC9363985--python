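"""Pipeline configuration and end-to-end orchestration.

One YAML-serializable config collects every threshold the analysis uses
(test levels, fold-change cutoff, CPM filter, mismap threshold, minimum
allele-assignable reads, CI level, Z threshold) plus the simulation seed.
``run_pipeline`` drives simulate/load -> normalize -> cluster -> modes ->
allele regression -> bias overlap and writes TSV artefacts with a manifest
carrying the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .aseqreg import ase_pipeline
from .biasoverlap import bias_overlap_analysis
from .cluster import dendrogram_to_newick, hier_cluster, pca, stabilized_log
from .containers import CountMatrix
from .diffexpr import nb_test
from .hetmodes import ModeClassifier
from .normalize import filter_low_expression, tmm_factors
from .synthdata import SimulationConfig, simulate_experiment, write_fixture


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    lfc: float = 1.0
    min_cpm: float = 1.0
    min_cpm_samples: int = 3
    mismap_threshold: float = 0.05
    min_allele_total: int = 10
    ci_level: float = 0.95
    z_threshold: float = 2.0
    n_boot: int = 200
    seed: int = 0
    simulate: bool = False
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")
        if not 0 <= self.mismap_threshold <= 1:
            raise ValueError("mismap_threshold must be in [0,1]")
        if self.min_allele_total < 1:
            raise ValueError("min_allele_total must be >= 1")
        if self.min_cpm < 0 or self.lfc < 0 or self.z_threshold < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_inputs(cfg: PipelineConfig, input_dir):
    """Load counts/samples/allele counts, or simulate them per config."""
    if cfg.simulate:
        sim_cfg = SimulationConfig(**{**cfg.sim, "seed": cfg.seed})
        cm, ac, samples, truth = simulate_experiment(sim_cfg)
        return cm, ac, samples, truth
    d = Path(input_dir)
    missing = [name for name in ("counts.tsv", "samples.tsv", "allele_counts.tsv")
               if not (d / name).exists()]
    if missing:
        raise FileNotFoundError(
            f"required inputs missing from {d}: {', '.join(missing)}")
    cm = hio.read_counts(d / "counts.tsv")
    samples = hio.read_samples(d / "samples.tsv")
    ac = hio.read_allele_counts(d / "allele_counts.tsv")
    return cm, ac, samples, None


def run_pipeline(cfg: PipelineConfig, input_dir=None, out_dir="results") -> Path:
    """Execute the full analysis; returns the result directory."""
    cfg.validate()
    out = hio.ensure_dir(out_dir)
    cm, ac, samples, truth = load_inputs(cfg, input_dir)
    if cfg.simulate:
        write_fixture((cm, ac, samples, truth), out / "simulated")

    cm = filter_low_expression(cm, cfg.min_cpm, cfg.min_cpm_samples)
    cm = cm.with_factors(tmm_factors(cm))
    pd.DataFrame({"sample_id": cm.sample_ids,
                  "lib_size": cm.lib_sizes,
                  "norm_factor": cm.norm_factors}).to_csv(
        out / "factors.tsv", sep="\t", index=False)

    log_mat = stabilized_log(cm)
    tree = hier_cluster(log_mat, n_boot=cfg.n_boot, seed=cfg.seed)
    (out / "tree.newick").write_text(dendrogram_to_newick(tree) + "\n")
    pc = pca(log_mat)
    pc["scores"].to_csv(out / "pca_scores.tsv", sep="\t")
    pc["variance_explained"].to_frame("fraction").to_csv(
        out / "pca_variance.tsv", sep="\t")

    mode_frames, reg_frames, bias_rows, mw_rows = [], [], [], []
    for lineage in samples["lineage"].unique():
        lin_samples = samples[samples["lineage"] == lineage]
        lin_cm = cm.subset_samples(lin_samples["sample_id"])

        clf = ModeClassifier(alpha=cfg.alpha).fit(lin_cm, lin_samples)
        calls = clf.calls_.copy()
        calls.insert(0, "lineage", lineage)
        mode_frames.append(calls)

        lin_ac = ac[ac["sample_id"].isin(lin_samples["sample_id"])]
        ase = ase_pipeline(lin_ac, lin_samples,
                           mismap_threshold=cfg.mismap_threshold,
                           min_total=cfg.min_allele_total,
                           ci_level=cfg.ci_level)
        for stage, reg in ase["regressions"].items():
            r = reg.copy()
            r.insert(0, "lineage", lineage)
            r.insert(1, "stage", stage)
            if "zscores" in ase and stage == "sexual":
                r = r.join(ase["zscores"][["z_slope", "z_intercept"]])
            reg_frames.append(r)
        if "mann_whitney" in ase:
            mw_rows.append({"lineage": lineage, **ase["mann_whitney"]})

        homo = lin_samples[lin_samples["karyotype"].isin(["homoA", "homoa"])]
        homo_cm = cm.subset_samples(homo["sample_id"])
        veg_homo = homo[homo["stage"] == "vegetative"]
        de_mat = nb_test(cm.subset_samples(veg_homo["sample_id"]),
                         veg_homo.set_index("sample_id")["karyotype"],
                         ("homoa", "homoA"))
        de_stage = nb_test(homo_cm, homo.set_index("sample_id")["stage"],
                           ("vegetative", "sexual"))
        res = bias_overlap_analysis(de_mat, de_stage, lfc_threshold=cfg.lfc)
        t = res["table"]
        bias_rows.append({
            "lineage": lineage,
            "veg_mat_a": t.iloc[0, 0], "veg_mat_A": t.iloc[0, 1],
            "sex_mat_a": t.iloc[1, 0], "sex_mat_A": t.iloc[1, 1],
            "chi2": res["chi2"], "p_value": res["p_value"],
        })

    pd.concat(mode_frames).to_csv(out / "modes.tsv", sep="\t", index=False)
    if reg_frames:
        pd.concat(reg_frames).to_csv(out / "regressions.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(bias_rows).to_csv(out / "table2.tsv", sep="\t", index=False)
    if mw_rows:
        pd.DataFrame(mw_rows).to_csv(out / "mann_whitney.tsv", sep="\t",
                                     index=False)

    manifest = {"config_hash": cfg.hash(), "seed": cfg.seed,
                "n_genes": int(cm.n_genes), "n_samples": int(cm.n_samples),
                "config": dataclasses.asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return out
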