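"""Clustering, marker genes and cell-type module scores.

Batch correction is deliberately out of scope: labels may be supplied
externally, or produced here by plain PCA + Leiden community detection as a
plumbing clusterer. Module scores follow the classic binned-control scheme
(mean expression of a gene set minus the mean of expression-bin-matched control
genes), which is what the classifier consumes as a cell-type-likeness feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData


def log_normalized(adata: AnnData, target_sum: float = 1e4) -> np.ndarray:
    """Dense ln(1 + CPM/100)-normalised expression (droplets x genes)."""
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    libsize = X.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    return np.log1p(X / libsize * target_sum)


def assign_clusters(
    adata: AnnData,
    n_pcs: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Leiden clustering on top PCs of log-normalised counts (deterministic per seed)."""
    import scanpy as sc

    work = AnnData(X=log_normalized(adata), obs=adata.obs[[]].copy())
    max_pcs = min(work.n_obs, work.n_vars) - 1
    if n_pcs > max_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {max_pcs}")
        n_pcs = max_pcs
    sc.pp.pca(work, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(work, n_pcs=n_pcs, random_state=seed)
    sc.tl.leiden(
        work,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return pd.Series(work.obs["leiden"].astype(str).to_numpy(), index=adata.obs_names, name="cluster")


def annotate_clusters(
    adata: AnnData,
    clusters: pd.Series,
    type_markers: dict[str, list[str]],
) -> pd.Series:
    """Map each cluster to the cell type whose canonical markers it expresses most.

    Per cluster, the mean log-normalised expression of each type's marker set is
    z-scored across clusters; the argmax type wins. Returns barcode -> type name.
    """
    X = log_normalized(adata)
    var_index = pd.Index(adata.var_names)
    cl = clusters.reindex(adata.obs_names)
    cluster_ids = sorted(cl.dropna().unique())
    scores = pd.DataFrame(index=cluster_ids, columns=list(type_markers), dtype=float)
    for ctype, genes in type_markers.items():
        cols = var_index.get_indexer([g for g in genes if g in var_index])
        if len(cols) == 0:
            raise ValueError(f"no marker genes of {ctype!r} present in the matrix")
        per_cell = X[:, cols].mean(axis=1)
        for cid in cluster_ids:
            scores.loc[cid, ctype] = per_cell[(cl == cid).to_numpy()].mean()
    z = (scores - scores.mean()) / scores.std().replace(0, 1.0)
    cluster_type = z.idxmax(axis=1)
    return cl.map(cluster_type).rename("cell_type")


def marker_genes(
    adata: AnnData,
    labels: pd.Series,
    top_n: int = 5,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> dict[str, list[str]]:
    """Top differentially expressed genes per cluster (one-vs-rest rank-sum test).

    Genes significant after Benjamini-Hochberg correction (adjusted p < alpha)
    are ranked by log fold-change; at most ``top_n`` are returned per cluster.
    Clusters with fewer than ``min_cells`` cells are skipped with a warning.
    """
    import scanpy as sc

    labels = labels.reindex(adata.obs_names)
    counts = labels.value_counts()
    keep_groups = [g for g in counts.index if counts[g] >= min_cells]
    for g in counts.index.difference(keep_groups):
        warnings.warn(f"cluster {g!r} has <{min_cells} cells; skipped")
    if len(keep_groups) < 2:
        raise ValueError("marker selection needs at least 2 clusters")
    mask = labels.isin(keep_groups).to_numpy()
    work = AnnData(X=log_normalized(adata)[mask], obs=pd.DataFrame(index=adata.obs_names[mask]))
    work.var_names = adata.var_names
    work.obs["group"] = labels[mask].astype(str).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(work, "group", method="wilcoxon", corr_method="benjamini-hochberg")
    out: dict[str, list[str]] = {}
    res = work.uns["rank_genes_groups"]
    for g in map(str, sorted(set(work.obs["group"]))):
        df = pd.DataFrame(
            {
                "gene": res["names"][g],
                "padj": res["pvals_adj"][g],
                "lfc": res["logfoldchanges"][g],
            }
        )
        sig = df[df["padj"] < alpha].sort_values("lfc", ascending=False)
        out[g] = sig["gene"].head(top_n).tolist()
    return out


def module_scores(
    adata: AnnData,
    gene_sets: dict[str, list[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned-control module score per droplet and gene set.

    score(cell, set) = mean log-norm expression of the set genes minus the mean
    over control genes; for every set gene, ``n_ctrl`` controls are drawn
    (seeded) from that gene's average-expression bin (``n_bins`` equal-frequency
    bins over all genes). Missing genes are dropped with a warning; a set that
    ends up empty yields a NaN column.
    """
    X = log_normalized(adata)
    var_index = pd.Index(adata.var_names)
    gene_means = X.mean(axis=0)
    n_bins = min(n_bins, len(var_index))
    bins = pd.qcut(pd.Series(gene_means).rank(method="first"), n_bins, labels=False)
    bin_members = {b: np.flatnonzero(bins.to_numpy() == b) for b in range(n_bins)}
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=adata.obs_names, dtype=float)
    for name in gene_sets:
        genes = [g for g in gene_sets[name] if g in var_index]
        dropped = set(gene_sets[name]) - set(genes)
        if dropped:
            warnings.warn(f"module {name!r}: dropping absent genes {sorted(dropped)}")
        if not genes:
            warnings.warn(f"module {name!r} empty after filtering; scores are NaN")
            out[name] = np.nan
            continue
        cols = var_index.get_indexer(genes)
        ctrl_cols: list[np.ndarray] = []
        for c in cols:
            members = bin_members[int(bins.iloc[c])]
            take = min(n_ctrl, len(members))
            ctrl_cols.append(rng.choice(members, size=take, replace=False))
        ctrl = np.unique(np.concatenate(ctrl_cols))
        out[name] = X[:, cols].mean(axis=1) - X[:, ctrl].mean(axis=1)
    return out
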