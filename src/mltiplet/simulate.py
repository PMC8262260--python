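"""Synthetic multi-omic droplet data and the doublet-spiking protocol.

Two generators live here:

1. :func:`generate_synthetic` builds a fully synthetic PBMC-like base dataset —
   negative-binomial RNA counts with planted cell-type markers, bimodal ADT
   counts, lineage-consistent VDJ chain capture, and an apoptotic subpopulation
   with an elevated mito / depressed ribo profile — with per-droplet ground
   truth, so the whole detection pipeline is testable without external data.
2. :func:`spike_doublets` applies the doublet-spiking protocol to any base
   dataset: after cleaning high-nUMI droplets (> median + IQR per sample),
   random cell pairs are sampled without replacement and their RNA, ADT and VDJ
   UMI counts summed into doublet droplets carrying the combined labels.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND5",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-CYB",
]
RIBO_GENES = [f"RPS{i}" for i in range(2, 10)] + [f"RPL{i}" for i in range(3, 11)]

DEFAULT_TYPE_MARKERS = {
    "B cell": ["MS4A1", "CD79A", "CD79B", "CD19", "BANK1", "TNFRSF13B", "IGHM", "BLK"],
    "T cell": ["CD3D", "CD3E", "CD3G", "TRAC", "TRBC2", "CD2", "IL7R", "LCK"],
    "myeloid": ["LYZ", "CD14", "FCGR3A", "S100A8", "S100A9", "FCN1", "CSF1R", "ITGAM"],
}

DEFAULT_ADT_POSITIVE_TYPES = {
    "CD19": ["B cell"],
    "CD3": ["T cell"],
    "CD4": ["T cell"],
    "CD8a": ["T cell"],
    "CD127": ["T cell"],
    "CD56": [],  # no NK population simulated: stays background everywhere
    "CD14": ["myeloid"],
    "CD16": ["myeloid"],
    # background / isotype-control antibodies: never positive, but they keep
    # the per-droplet CLR denominator stable (as they do in real panels)
    "CD34": [],
    "CD138": [],
    "TCRgd": [],
    "IgG1": [],
    "IgG2a": [],
    "IgG2b": [],
}

#: fraction of positive-type cells actually positive (T subsets); 1.0 elsewhere
DEFAULT_ADT_POSITIVE_PROB = {"CD4": 0.6, "CD8a": 0.4}

#: mutually exclusive cross-lineage pairs resolvable on the synthetic panel
DEFAULT_SYNTH_PAIRS = (
    ("CD19", "CD3"), ("CD19", "CD4"), ("CD19", "CD8a"), ("CD19", "CD56"),
    ("CD19", "CD16"), ("CD19", "CD14"), ("CD19", "CD127"),
    ("CD4", "CD16"), ("CD127", "CD16"), ("CD127", "CD14"),
    ("CD3", "CD14"), ("CD3", "CD16"),
)

V_GENES = {
    "IGH": ["IGHV1-2", "IGHV3-23", "IGHV4-34", "IGHV1-69"],
    "IGK": ["IGKV1-39", "IGKV3-20", "IGKV4-1"],
    "IGL": ["IGLV1-44", "IGLV2-14"],
    "TRA": ["TRAV1-2", "TRAV8-4", "TRAV12-1"],
    "TRB": ["TRBV20-1", "TRBV7-9", "TRBV5-1"],
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SynthConfig:
    """Study conditions of the synthetic generator.

    Defaults model a PBMC-like mixture of three broad immune cell types with
    moderately overdispersed counts, clearly bimodal ADT markers, realistic VDJ
    capture rates, and a small apoptotic subpopulation kept below the 25%-mito
    QC bound.
    """

    n_cells: dict = field(
        default_factory=lambda: {"B cell": 1500, "T cell": 2000, "myeloid": 1500}
    )
    sample_ids: tuple = ("S1",)
    n_housekeeping: int = 940
    housekeeping_mean: float = 2.2
    housekeeping_sigma: float = 0.5  # lognormal spread of per-gene base means
    marker_mean: float = 20.0
    marker_background: float = 0.2
    mito_mean: float = 18.0  # per mito gene, healthy cells (~6% of UMIs)
    ribo_mean: float = 37.5  # per ribo gene, healthy cells (~20% of UMIs)
    dispersion: float = 2.0  # NB shape; smaller = more overdispersed
    library_sigma: float = 0.3  # lognormal cell-size factor
    apoptotic_fraction: float = 0.05
    apoptotic_mito_factor: float = 3.0
    apoptotic_ribo_factor: float = 0.3
    adt_positive_types: dict = field(
        default_factory=lambda: dict(DEFAULT_ADT_POSITIVE_TYPES)
    )
    adt_positive_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_ADT_POSITIVE_PROB)
    )
    adt_pos_mean: float = 300.0
    adt_neg_mean: float = 8.0
    adt_pos_shape: float = 8.0
    adt_neg_shape: float = 10.0
    capture_igh: float = 0.85
    capture_light: float = 0.85
    p_igk: float = 0.6  # light chain is IGK (else IGL)
    capture_tra: float = 0.80
    capture_trb: float = 0.85
    dual_tra_prob: float = 0.03
    productive_prob: float = 0.93
    contig_umi_mean: float = 12.0  # Poisson; leaves a small tail under the >=6 filter
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.apoptotic_fraction, self.capture_igh, self.capture_light,
            self.p_igk, self.capture_tra, self.capture_trb,
            self.dual_tra_prob, self.productive_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(n <= 0 for n in self.n_cells.values()):
            raise ValueError("cell counts must be positive")


@dataclass
class MultiomicDataset:
    """RNA (AnnData, droplets x genes), ADT counts, contig table, plus truth in obs."""

    rna: AnnData
    adt: pd.DataFrame
    contigs: pd.DataFrame

    @property
    def barcodes(self) -> pd.Index:
        return self.rna.obs_names

    def subset(self, barcodes) -> "MultiomicDataset":
        barcodes = pd.Index(barcodes)
        return MultiomicDataset(
            rna=self.rna[barcodes].copy(),
            adt=self.adt.loc[barcodes],
            contigs=self.contigs[self.contigs["barcode"].isin(barcodes)].reset_index(drop=True),
        )


def _random_cdr3(rng: np.random.Generator, length: int = 12) -> str:
    return "C" + "".join(rng.choice(_AA, size=length - 2)) + "F"


def _nb_counts(rng, mean_matrix, dispersion):
    lam = rng.gamma(shape=dispersion, scale=mean_matrix / dispersion)
    return rng.poisson(lam)


def generate_synthetic(config: SynthConfig | None = None, seed: int | None = None) -> MultiomicDataset:
    """Generate the synthetic base dataset (deterministic per seed)."""
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    types = list(cfg.n_cells)
    markers = {t: list(g) for t, g in DEFAULT_TYPE_MARKERS.items() if t in types}
    for t in types:
        markers.setdefault(t, [f"{t.upper().replace(' ', '')}MK{i}" for i in range(1, 9)])
    hk_genes = [f"HK{i:04d}" for i in range(1, cfg.n_housekeeping + 1)]
    genes = (
        sum((markers[t] for t in types), []) + MITO_GENES + RIBO_GENES + hk_genes
    )
    gene_idx = pd.Index(genes)

    hk_means = rng.lognormal(
        mean=np.log(cfg.housekeeping_mean), sigma=cfg.housekeeping_sigma,
        size=cfg.n_housekeeping,
    )

    # per-type expected expression per gene
    mu_by_type = {}
    for t in types:
        mu = np.empty(len(genes))
        for u in types:
            cols = gene_idx.get_indexer(markers[u])
            mu[cols] = cfg.marker_mean if u == t else cfg.marker_background
        mu[gene_idx.get_indexer(MITO_GENES)] = cfg.mito_mean
        mu[gene_idx.get_indexer(RIBO_GENES)] = cfg.ribo_mean
        mu[gene_idx.get_indexer(hk_genes)] = hk_means
        mu_by_type[t] = mu

    mito_cols = gene_idx.get_indexer(MITO_GENES)
    ribo_cols = gene_idx.get_indexer(RIBO_GENES)

    blocks, obs_rows, barcodes = [], [], []
    adt_rows = []
    contig_rows = []
    adt_panel = list(cfg.adt_positive_types)
    cell_counter = 0
    for t in types:
        n = cfg.n_cells[t]
        mu = np.tile(mu_by_type[t], (n, 1))
        apoptotic = rng.random(n) < cfg.apoptotic_fraction
        mu[np.ix_(apoptotic, mito_cols)] *= cfg.apoptotic_mito_factor
        mu[np.ix_(apoptotic, ribo_cols)] *= cfg.apoptotic_ribo_factor
        libfac = rng.lognormal(mean=0.0, sigma=cfg.library_sigma, size=n)
        mu *= libfac[:, None]
        blocks.append(_nb_counts(rng, mu, cfg.dispersion))

        samples = [cfg.sample_ids[i % len(cfg.sample_ids)] for i in range(n)]
        for i in range(n):
            bc = f"CELL{cell_counter:05d}-{samples[i]}"
            cell_counter += 1
            barcodes.append(bc)
            obs_rows.append(
                {"sample_id": samples[i], "cell_type_truth": t, "apoptotic": bool(apoptotic[i])}
            )
            # ADT: bimodal per marker, consistent with the cell type
            row = {}
            for ab in adt_panel:
                positive = t in cfg.adt_positive_types[ab] and (
                    rng.random() < cfg.adt_positive_prob.get(ab, 1.0)
                )
                mean = cfg.adt_pos_mean if positive else cfg.adt_neg_mean
                shape = cfg.adt_pos_shape if positive else cfg.adt_neg_shape
                row[ab] = int(rng.poisson(rng.gamma(shape, mean / shape)))
            adt_rows.append(row)
            # VDJ: B cells carry IGH + one light chain; T cells TRA + TRB
            contig_rows.extend(_cell_contigs(rng, cfg, bc, t))

    X = np.vstack(blocks).astype(np.float64)
    obs = pd.DataFrame(obs_rows, index=pd.Index(barcodes, name="barcode"))
    rna = AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_idx))
    adt = pd.DataFrame(adt_rows, index=obs.index, columns=adt_panel)
    contigs = pd.DataFrame(
        contig_rows, columns=["barcode", "chain", "productive", "umis", "v_gene", "cdr3"]
    )
    contigs["usable"] = True
    return MultiomicDataset(rna=rna, adt=adt, contigs=contigs)


def _cell_contigs(rng, cfg: SynthConfig, barcode: str, cell_type: str) -> list:
    def one(chain):
        return (
            barcode,
            chain,
            bool(rng.random() < cfg.productive_prob),
            int(rng.poisson(cfg.contig_umi_mean)),
            str(rng.choice(V_GENES[chain])),
            _random_cdr3(rng),
        )

    rows = []
    if cell_type == "B cell":
        if rng.random() < cfg.capture_igh:
            rows.append(one("IGH"))
        if rng.random() < cfg.capture_light:
            rows.append(one("IGK" if rng.random() < cfg.p_igk else "IGL"))
    elif cell_type == "T cell":
        if rng.random() < cfg.capture_tra:
            rows.append(one("TRA"))
            if rng.random() < cfg.dual_tra_prob:
                rows.append(one("TRA"))
        if rng.random() < cfg.capture_trb:
            rows.append(one("TRB"))
    return rows


def clean_base(dataset: MultiomicDataset) -> MultiomicDataset:
    """Drop droplets with nUMI strictly above median + IQR, per sample.

    Quartiles use linear interpolation (numpy default, type 7). Idempotent in
    practice only approximately — re-cleaning recomputes the cut on the cleaned
    sample — so the pipeline cleans exactly once before spiking.
    """
    n_umi = pd.Series(
        np.asarray(dataset.rna.X).sum(axis=1), index=dataset.barcodes
    )
    sample = dataset.rna.obs.get(
        "sample_id", pd.Series("sample0", index=dataset.barcodes)
    )
    keep = pd.Series(True, index=dataset.barcodes)
    for _, idx in n_umi.groupby(sample).groups.items():
        x = n_umi.loc[idx]
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        keep.loc[idx] = x <= med + (q3 - q1)
    return dataset.subset(dataset.barcodes[keep])


def _n_doublets(n_cells: int, proportion: float) -> int:
    # D doublets consume 2 cells each: N_out = N - D and D = round(p * N_out)
    d = int(round(proportion * n_cells / (1.0 + proportion)))
    for cand in (d - 1, d, d + 1):
        if cand >= 0 and cand == round(proportion * (n_cells - cand)):
            return cand
    return d


def spike_doublets(
    dataset: MultiomicDataset,
    proportion: float,
    seed: int = 0,
    within_sample: bool = True,
) -> tuple[MultiomicDataset, pd.DataFrame]:
    """Create doublets by sampling cell pairs and summing their counts.

    ``proportion`` is the fraction of *output* droplets that are doublets.
    Constituents are sampled without replacement (within sample by default) and
    removed; each doublet droplet's RNA, ADT and VDJ records are the exact sums
    / union of its constituents'. Returns the spiked dataset and a truth table
    (one row per output droplet: constituents, types, is_doublet, subtype).
    """
    if not 0.0 <= proportion < 0.5:
        raise ValueError("proportion must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(dataset.barcodes)
    n_doublets = _n_doublets(n, proportion)
    obs = dataset.rna.obs
    sample = obs.get("sample_id", pd.Series("sample0", index=dataset.barcodes))

    if n_doublets == 0:
        truth = _truth_table(dataset, [], [])
        return dataset.subset(dataset.barcodes), truth

    if within_sample:
        groups = list(pd.Index(dataset.barcodes).groupby(sample).items())
    else:
        groups = [("all", pd.Index(dataset.barcodes))]
    # allocate doublets across samples proportionally (largest remainder)
    sizes = np.array([len(idx) for _, idx in groups], dtype=float)
    exact = n_doublets * sizes / sizes.sum()
    alloc = np.floor(exact).astype(int)
    for i in np.argsort(exact - alloc)[::-1][: n_doublets - alloc.sum()]:
        alloc[i] += 1
    if any(2 * a > len(idx) for a, (_, idx) in zip(alloc, groups)):
        raise ValueError("not enough cells to form the requested doublets")

    pairs = []
    for a, (_, idx) in zip(alloc, groups):
        chosen = rng.choice(np.asarray(idx), size=2 * a, replace=False)
        pairs.extend([(chosen[2 * i], chosen[2 * i + 1]) for i in range(a)])

    return _merge_pairs(dataset, pairs, sample)


def _merge_pairs(dataset, pairs, sample):
    consumed = {bc for p in pairs for bc in p}
    keep = [bc for bc in dataset.barcodes if bc not in consumed]
    pos = {bc: i for i, bc in enumerate(dataset.barcodes)}
    X = np.asarray(dataset.rna.X)
    obs = dataset.rna.obs

    dbl_rows, dbl_obs, dbl_barcodes, dbl_adt = [], [], [], []
    contig_map = {}
    for i, (b1, b2) in enumerate(pairs):
        new_bc = f"DBL{i:05d}-{sample[b1]}"
        dbl_barcodes.append(new_bc)
        dbl_rows.append(X[pos[b1]] + X[pos[b2]])
        t1, t2 = obs.loc[b1, "cell_type_truth"], obs.loc[b2, "cell_type_truth"]
        dbl_obs.append(
            {
                "sample_id": sample[b1],
                "cell_type_truth": "+".join(sorted([t1, t2])),
                "apoptotic": bool(obs.loc[b1, "apoptotic"] or obs.loc[b2, "apoptotic"]),
            }
        )
        dbl_adt.append(dataset.adt.loc[b1] + dataset.adt.loc[b2])
        contig_map[b1] = new_bc
        contig_map[b2] = new_bc

    keep_idx = [pos[bc] for bc in keep]
    new_X = np.vstack([X[keep_idx], np.vstack(dbl_rows)]) if pairs else X[keep_idx]
    new_obs = pd.concat(
        [obs.loc[keep, ["sample_id", "cell_type_truth", "apoptotic"]],
         pd.DataFrame(dbl_obs, index=pd.Index(dbl_barcodes, name="barcode"))]
    )
    rna = AnnData(X=new_X, obs=new_obs, var=dataset.rna.var.copy())
    adt = pd.concat(
        [dataset.adt.loc[keep], pd.DataFrame(dbl_adt, index=pd.Index(dbl_barcodes))]
    )
    contigs = dataset.contigs.copy()
    moved = contigs["barcode"].map(contig_map)
    contigs["barcode"] = moved.where(moved.notna(), contigs["barcode"])
    contigs = contigs[contigs["barcode"].isin(new_obs.index)].reset_index(drop=True)
    spiked = MultiomicDataset(rna=rna, adt=adt, contigs=contigs)
    truth = _truth_table(dataset, pairs, dbl_barcodes)
    return spiked, truth


def _truth_table(dataset, pairs, dbl_barcodes) -> pd.DataFrame:
    obs = dataset.rna.obs
    consumed = {bc for p in pairs for bc in p}
    rows = []
    for bc in dataset.barcodes:
        if bc in consumed:
            continue
        t = obs.loc[bc, "cell_type_truth"]
        rows.append(
            {
                "barcode": bc, "is_doublet": False, "constituents": bc,
                "constituent_types": t, "pair_label": t, "subtype": "singlet",
            }
        )
    for new_bc, (b1, b2) in zip(dbl_barcodes, pairs):
        t1, t2 = obs.loc[b1, "cell_type_truth"], obs.loc[b2, "cell_type_truth"]
        ts = sorted([t1, t2])
        rows.append(
            {
                "barcode": new_bc, "is_doublet": True,
                "constituents": f"{b1}|{b2}",
                "constituent_types": "|".join([t1, t2]),
                "pair_label": "+".join(ts),
                "subtype": "homotypic" if t1 == t2 else "heterotypic",
            }
        )
    return pd.DataFrame(rows).set_index("barcode")


def score_detection(
    calls: pd.Series, truth: pd.DataFrame, min_group: int = 5
) -> tuple[pd.DataFrame, float]:
    """Per-constituent-pair sensitivity and overall singlet specificity.

    Only pairs with strictly more than ``min_group`` planted doublets are
    scored. ``calls`` is a boolean doublet-call series; barcodes absent from it
    count as negative calls.
    """
    calls = calls.reindex(truth.index)
    calls = calls.where(calls.notna(), False).astype(bool)
    doublets = truth[truth["is_doublet"]]
    rows = []
    for label, grp in doublets.groupby("pair_label"):
        if len(grp) > min_group:
            rows.append(
                {
                    "pair_label": label,
                    "subtype": grp["subtype"].iloc[0],
                    "n_planted": len(grp),
                    "sensitivity": float(calls.loc[grp.index].mean()),
                }
            )
    singlets = truth.index[~truth["is_doublet"]]
    specificity = float((~calls.loc[singlets]).mean()) if len(singlets) else float("nan")
    table = pd.DataFrame(rows, columns=["pair_label", "subtype", "n_planted", "sensitivity"])
    return table.set_index("pair_label"), specificity
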