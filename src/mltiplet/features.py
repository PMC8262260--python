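"""Per-droplet classifier covariates: mito-ribo ratio and per-sample CLR transforms.

The design-matrix rows of the doublet classifier are assembled here: library-size
covariates (nUMI, nGenes, VDJ UMIs) are centred-log-ratio (CLR) transformed across
the droplets of each sample, and the apoptosis covariate is the mito-ribo ratio
m/(m+r), where m and r are the per-droplet mitochondrial and ribosomal-protein
UMI percentages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData

from .io import qc_metrics


def mito_ribo_ratio(pct_mito, pct_ribo):
    """Apoptosis score m/(m+r) in [0, 1]; defined as 0 when m = r = 0.

    Elevated in apoptotic/low-quality droplets, which lose ribosomal-protein
    transcripts while retaining mitochondrial ones.
    """
    m = np.asarray(pct_mito, dtype=float)
    r = np.asarray(pct_ribo, dtype=float)
    if (m < 0).any() or (r < 0).any():
        raise ValueError("percentages must be non-negative")
    denom = m + r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def clr_vector(x, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio: y_i = ln(x_i + c) - mean_j ln(x_j + c); sums to 0."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("CLR needs at least 2 values")
    if (x < 0).any():
        raise ValueError("CLR input must be non-negative")
    logs = np.log(x + pseudocount)
    return logs - logs.mean()


def clr_adt(
    counts: pd.DataFrame,
    sample_ids: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """CLR-normalise ADT counts per droplet across antibodies, sample-wise.

    ``counts`` is barcodes x antibodies. The transform is applied within each
    sample independently; since the margin is per droplet the blocks are
    numerically independent anyway, which the per-sample contract makes explicit.
    """
    if counts.shape[1] < 2:
        warnings.warn("single-antibody panel: CLR is degenerate (all zeros)")
        return counts.astype(float) * 0.0
    if sample_ids is None:
        sample_ids = pd.Series("sample0", index=counts.index)
    out = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for _, idx in counts.groupby(sample_ids.reindex(counts.index)).groups.items():
        block = counts.loc[idx].to_numpy(dtype=float)
        logs = np.log(block + pseudocount)
        out.loc[idx] = logs - logs.mean(axis=1, keepdims=True)
    return out


def compute_droplet_features(
    adata: AnnData,
    contigs: pd.DataFrame | None = None,
    mito_regex: str = r"^MT-",
    ribo_regex: str = r"^RP[SL]",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-droplet feature table used by the doublet classifier.

    Columns: n_genes, n_umi, pct_mito, pct_ribo, mito_ribo_ratio, n_umi_vdj,
    and per-sample CLR transforms clr_n_umi, clr_n_genes, clr_n_umi_vdj.
    ``contigs`` should already be filtered (productive, UMI >= 6); droplets with
    no captured chains get n_umi_vdj = 0, which enters the CLR with the
    pseudocount rather than as missing.
    """
    feats = qc_metrics(adata, mito_regex=mito_regex, ribo_regex=ribo_regex)
    feats["mito_ribo_ratio"] = mito_ribo_ratio(
        feats["pct_mito"].to_numpy(), feats["pct_ribo"].to_numpy()
    )
    if contigs is not None and len(contigs):
        vdj = contigs.groupby("barcode")["umis"].sum()
        feats["n_umi_vdj"] = vdj.reindex(feats.index).fillna(0).astype(int)
    else:
        feats["n_umi_vdj"] = 0
    sample = adata.obs.get("sample_id", pd.Series("sample0", index=feats.index))
    feats["sample_id"] = np.asarray(sample)
    for col in ("n_umi", "n_genes", "n_umi_vdj"):
        feats[f"clr_{col}"] = 0.0
        for _, idx in feats.groupby("sample_id").groups.items():
            feats.loc[idx, f"clr_{col}"] = clr_vector(
                feats.loc[idx, col].to_numpy(), pseudocount=pseudocount
            )
    return feats
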