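"""Expression-profile similarity: variance-stabilized log transform,
Euclidean hierarchical clustering with gene-bootstrap support, and PCA.

The transform is a prior-count log-CPM (the pseudo-count rescaled per
library so deep and shallow libraries get comparable damping) — a
documented substitute for a shrinkage-GLM regularized log, adequate here
because the clustering conclusions are topological, not numeric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .containers import CountMatrix
from .normalize import cpm


def stabilized_log(cm: CountMatrix, prior_count: float = 4.0) -> pd.DataFrame:
    """log2 CPM with a library-rescaled prior count (genes x samples)."""
    eff = cm.effective_lib_sizes().to_numpy(dtype=float)
    prior = prior_count * eff / eff.mean()
    y = cm.counts.to_numpy(dtype=float)
    vals = np.log2((y + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


def _clusters_from_linkage(Z: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Leaf sets of every internal node of a scipy linkage matrix."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n_leaves + k] = merged
        out.append(merged)
    return out


def hier_cluster(matrix: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                 linkage_method: str = "average") -> dict:
    """Euclidean hierarchical clustering of samples with bootstrap support.

    ``matrix`` is genes x samples (typically :func:`stabilized_log` output).
    Distances are Euclidean over genes; agglomeration is average linkage by
    default. Support of each internal node is the percentage of gene
    bootstrap replicates in which the node's leaf set recurs.
    """
    samples = list(matrix.columns)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage_method)
    nodes = _clusters_from_linkage(Z, n)

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(nodes))
    G = X.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, G, G)
        Zb = hierarchy.linkage(pdist(X[:, idx], metric="euclidean"),
                               method=linkage_method)
        boot_nodes = set(_clusters_from_linkage(Zb, n))
        for i, node in enumerate(nodes):
            if node in boot_nodes:
                hits[i] += 1
    support = 100.0 * hits / n_boot if n_boot > 0 else np.full(len(nodes), np.nan)
    return {"linkage": Z, "samples": samples, "nodes": nodes,
            "support": support}


def dendrogram_to_newick(result: dict) -> str:
    """Serialize a hier_cluster result as Newick; internal node labels are
    bootstrap support percentages, branch lengths are merge heights."""
    Z = result["linkage"]
    samples = result["samples"]
    support = result["support"]
    n = len(samples)
    height = {i: 0.0 for i in range(n)}

    def name(i: int) -> str:
        return str(samples[i]).replace(" ", "_").replace(",", "_")

    def build(node: int) -> str:
        if node < n:
            return name(node)
        k = node - n
        a, b, h, _ = Z[k]
        height[node] = h
        left = build(int(a)) + f":{h - height[int(a)]:.6g}"
        right = build(int(b)) + f":{h - height[int(b)]:.6g}"
        label = f"{support[k]:.1f}" if np.isfinite(support[k]) else ""
        return f"({left},{right}){label}"

    return build(2 * n - 2) + ";"


def pca(matrix: pd.DataFrame, n_components: int = 3) -> dict:
    """Centered-gene PCA of samples.

    Returns scores (samples x components), loadings (genes x components)
    and the variance-explained fractions (decreasing, summing to <= 1).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    n_components = min(n_components, matrix.shape[1] - 1, matrix.shape[0])
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return {
        "scores": pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        "loadings": pd.DataFrame(model.components_.T, index=matrix.index,
                                 columns=comp_names),
        "variance_explained": pd.Series(model.explained_variance_ratio_,
                                        index=comp_names),
    }
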