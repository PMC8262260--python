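"""Readers/writers for droplet count matrices and VDJ contig tables.

Expression data live in :class:`anndata.AnnData` (droplets in ``obs``, genes in
``var``); antibody-capture (ADT) counts in a barcode x antibody DataFrame; VDJ
contigs in a long DataFrame following the 10x ``filtered_contig_annotations.csv``
dialect.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

VALID_CHAINS = ("IGH", "IGK", "IGL", "TRA", "TRB")

#: column spec of the 10x contig annotation dialect we require
CONTIG_REQUIRED_COLUMNS = ("barcode", "chain", "productive", "umis")

_TRUE_STRINGS = {"true"}


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def _validate_counts(counts: np.ndarray | sp.spmatrix) -> None:
    data = counts.data if sp.issparse(counts) else np.asarray(counts)
    if data.size and data.min() < 0:
        raise FormatError("counts must be non-negative")
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError("counts must be integral UMI counts")


def read_expression(
    path: str | Path,
    format_hint: str | None = None,
    sample_id: str | None = None,
) -> AnnData:
    """Read a UMI count matrix as AnnData (barcodes x genes).

    Supported formats: a Matrix Market triplet directory (``matrix.mtx`` +
    ``features.tsv`` + ``barcodes.tsv``), 10x HDF5, or a dense CSV with genes as
    rows and barcodes as columns.  If ``sample_id`` is given, barcodes are
    suffixed ``-{sample_id}`` so they stay globally unique across samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix in {".h5", ".hdf5"}:
            fmt = "10x_h5"
        elif path.suffix == ".csv":
            fmt = "csv"
        else:
            raise FormatError(f"cannot infer format of {path}")

    if fmt == "mtx":
        adata = _read_mtx_dir(path)
    elif fmt == "10x_h5":
        import scanpy as sc

        adata = sc.read_10x_h5(path)
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        if df.empty:
            raise FormatError(f"{path} holds an empty matrix")
        adata = AnnData(
            X=df.to_numpy(dtype=np.float64).T,
            obs=pd.DataFrame(index=df.columns.astype(str)),
            var=pd.DataFrame(index=df.index.astype(str)),
        )
    else:
        raise FormatError(f"unknown format hint {fmt!r}")

    if adata.n_obs == 0 or adata.n_vars == 0:
        raise FormatError(f"{path}: empty matrix")
    _validate_counts(adata.X)
    if sample_id is not None:
        adata.obs_names = [f"{b}-{sample_id}" for b in adata.obs_names]
    adata.obs["sample_id"] = sample_id if sample_id is not None else "sample0"
    if adata.obs_names.duplicated().any():
        raise FormatError("duplicate barcodes within sample")
    return adata


def _read_mtx_dir(path: Path) -> AnnData:
    mtx = path / "matrix.mtx"
    feat = path / "features.tsv"
    if not feat.exists():
        feat = path / "genes.tsv"
    barc = path / "barcodes.tsv"
    for p in (mtx, feat, barc):
        if not p.exists():
            raise FormatError(f"missing {p.name} in MTX directory {path}")
    try:
        mat = scipy.io.mmread(str(mtx))
    except Exception as exc:  # malformed header etc.
        raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barc, sep="\t", header=None)[0].astype(str).tolist()
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} inconsistent with {len(genes)} features "
            f"x {len(barcodes)} barcodes"
        )
    return AnnData(
        X=mat.T.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_expression(adata: AnnData, path: str | Path) -> None:
    """Write an MTX triplet directory (genes x barcodes, 10x orientation)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if not sp.issparse(X) else X.T)
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def _parse_productive(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    # 10x dialects: "True"/"true"/"TRUE" vs "False"/"None"/"" etc.
    return str(value).strip().lower() in _TRUE_STRINGS


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Parse a 10x-style contig annotation CSV into a tidy contig table.

    Returns columns ``barcode, chain, productive, umis, v_gene, cdr3, usable``.
    Records with chains outside IGH/IGK/IGL/TRA/TRB (e.g. "Multi") are retained
    but flagged ``usable=False`` and are excluded by downstream filtering.
    """
    df = pd.read_csv(path)
    missing = [c for c in CONTIG_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table missing required columns: {missing}")
    out = pd.DataFrame(
        {
            "barcode": df["barcode"].astype(str),
            "chain": df["chain"].astype(str),
            "productive": df["productive"].map(_parse_productive),
            "umis": pd.to_numeric(df["umis"]).astype(int),
            "v_gene": df.get("v_gene", pd.Series("", index=df.index)).astype(str),
            "cdr3": df.get("cdr3", pd.Series("", index=df.index)).astype(str),
        }
    )
    if (out["umis"] < 0).any():
        raise FormatError("negative UMI count in contig table")
    out["usable"] = out["chain"].isin(VALID_CHAINS)
    return out


def write_contigs(contigs: pd.DataFrame, path: str | Path) -> None:
    cols = ["barcode", "chain", "productive", "umis", "v_gene", "cdr3"]
    contigs[cols].to_csv(path, index=False)


def _matrix_stats(adata: AnnData, gene_mask: np.ndarray | None = None):
    X = adata.X
    if sp.issparse(X):
        if gene_mask is None:
            return np.asarray((X > 0).sum(axis=1)).ravel(), np.asarray(X.sum(axis=1)).ravel()
        sub = X[:, gene_mask]
        return None, np.asarray(sub.sum(axis=1)).ravel()
    X = np.asarray(X)
    if gene_mask is None:
        return (X > 0).sum(axis=1), X.sum(axis=1)
    return None, X[:, gene_mask].sum(axis=1)


def qc_metrics(
    adata: AnnData,
    mito_regex: str = r"^MT-",
    ribo_regex: str = r"^RP[SL]",
) -> pd.DataFrame:
    """Per-droplet nGenes, nUMI, %mito and %ribo."""
    n_genes, n_umi = _matrix_stats(adata)
    mito_mask = np.asarray(adata.var_names.str.contains(mito_regex, regex=True))
    ribo_mask = np.asarray(adata.var_names.str.contains(ribo_regex, regex=True))
    _, mito_umi = _matrix_stats(adata, mito_mask)
    _, ribo_umi = _matrix_stats(adata, ribo_mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / n_umi, 0.0)
        pct_ribo = np.where(n_umi > 0, 100.0 * ribo_umi / n_umi, 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_umi": n_umi.astype(int),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
        },
        index=adata.obs_names,
    )


def qc_filter(
    adata: AnnData,
    min_genes: int = 500,
    min_umi: int = 1000,
    max_pct_mito: float = 25.0,
    mito_regex: str = r"^MT-",
) -> pd.Index:
    """Return barcodes passing droplet QC.

    A droplet is retained iff n_genes > min_genes AND n_umi > min_umi AND
    pct_mito < max_pct_mito — strict inequalities on every bound.
    """
    m = qc_metrics(adata, mito_regex=mito_regex)
    keep = (
        (m["n_genes"] > min_genes)
        & (m["n_umi"] > min_umi)
        & (m["pct_mito"] < max_pct_mito)
    )
    retained = m.index[keep]
    if len(retained) == 0:
        raise ValueError("QC filter retained zero barcodes")
    return retained


def apply_qc(adata: AnnData, **kwargs) -> AnnData:
    """Subset an AnnData to the QC-passing barcodes (copy)."""
    return adata[qc_filter(adata, **kwargs)].copy()
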