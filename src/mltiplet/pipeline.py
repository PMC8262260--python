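"""End-to-end orchestration: read -> QC -> labels -> CITE flags -> VDJ flags ->
features -> train -> predict -> write.

`run_synthetic_benchmark` runs the identical stage sequence on a generated
dataset with planted doublets and scores the calls against ground truth;
`run_pipeline` is the file-based variant driven by a YAML config.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, cite, classifier, features, io, simulate, vdj

log = logging.getLogger("mltiplet")


def _antibody_map_from_types(adt_positive_types: dict, all_types) -> dict:
    all_types = set(all_types)
    return {
        ab: {"pos": sorted(pos), "neg": sorted(all_types - set(pos))}
        for ab, pos in adt_positive_types.items()
    }


def detect_doublets(
    dataset: simulate.MultiomicDataset,
    labels: pd.Series | None = None,
    type_markers: dict | None = None,
    adt_positive_types: dict | None = None,
    exclusive_pairs=None,
    b_cell_types=("B cell",),
    t_cell_types=("T cell",),
    sources=("vdj", "cite"),
    cutoff: float = 0.5,
    seed: int = 0,
    qc_kwargs: dict | None = None,
    clustering_kwargs: dict | None = None,
    minimal_features: bool = False,
) -> dict:
    """Run the full detection pipeline on an in-memory multi-omic dataset.

    When ``labels`` is None, droplets are clustered (PCA + Leiden) and clusters
    are annotated to broad types via ``type_markers``. Returns a dict with the
    final call table, the fitted model, per-stage counts, and intermediates.
    """
    report = {}
    rna = dataset.rna

    # --- QC ---------------------------------------------------------------
    retained = io.qc_filter(rna, **(qc_kwargs or {}))
    ds = dataset.subset(retained)
    report["n_input"] = int(rna.n_obs)
    report["n_after_qc"] = int(len(retained))
    log.info("QC retained %d/%d droplets", len(retained), rna.n_obs)

    # --- labels -------------------------------------------------------------
    clusters = annotation.assign_clusters(ds.rna, seed=seed, **(clustering_kwargs or {}))
    if labels is None:
        if type_markers is None:
            raise ValueError("need type_markers to annotate clusters (or pass labels)")
        labels = annotation.annotate_clusters(ds.rna, clusters, type_markers)
    else:
        labels = labels.reindex(ds.barcodes)
    report["n_clusters"] = int(clusters.nunique())

    # --- CITE-seq flags -----------------------------------------------------
    calls = {}
    cite_table = None
    if "cite" in sources and ds.adt is not None and len(ds.adt.columns) >= 2:
        clr = features.clr_adt(ds.adt, sample_ids=ds.rna.obs["sample_id"])
        if adt_positive_types is None:
            raise ValueError("need adt_positive_types for the CITE source")
        ab_map = _antibody_map_from_types(adt_positive_types, labels.dropna().unique())
        refs = cite.reference_populations(labels, ab_map)
        caller = cite.AdtPositivityCaller().fit(clr, refs)
        positivity = caller.transform(clr)
        pairs = exclusive_pairs if exclusive_pairs is not None else cite.DEFAULT_EXCLUSIVE_PAIRS
        cite_table = cite.flag_cite_doublets(positivity, pairs, usable=caller.usable_)
        calls["cite"] = cite_table["flag"]
        report["n_cite_flagged"] = int(cite_table["flag"].sum())
        report["adt_usable"] = {k: bool(v) for k, v in caller.usable_.items()}

    # --- VDJ flags ----------------------------------------------------------
    vdj_table = None
    kept_contigs = vdj.filter_contigs(ds.contigs) if ds.contigs is not None else None
    if "vdj" in sources and kept_contigs is not None:
        vdj_table = vdj.identify_vdj_doublets(
            kept_contigs, labels, b_cell_types=b_cell_types, t_cell_types=t_cell_types
        )
        calls["vdj"] = vdj_table["flag"].reindex(ds.barcodes).fillna(False)
        report["n_vdj_flagged"] = int(vdj_table["flag"].sum())

    if not calls:
        raise ValueError("no doublet source produced flags; nothing to train on")

    # --- features -----------------------------------------------------------
    feats = features.compute_droplet_features(ds.rna, contigs=kept_contigs)
    sets = annotation.marker_genes(ds.rna, clusters, top_n=5)
    sets = {k: v for k, v in sets.items() if v}
    scores = annotation.module_scores(ds.rna, sets, seed=seed)
    score_cols = [f"score_{c}" for c in scores.columns]
    feats[score_cols] = scores.to_numpy()

    # --- train + predict ----------------------------------------------------
    call_frame = pd.DataFrame(calls).reindex(ds.barcodes).fillna(False)
    training = classifier.build_training_set(call_frame)
    # design matrix: the four QC covariates carried through trimming plus the
    # module scores; `minimal_features` restricts it to mito-ribo ratio,
    # CLR nUMI and module scores
    feature_names = ["mito_ribo_ratio", "clr_n_umi", "clr_n_genes", "clr_n_umi_vdj"] + score_cols
    if minimal_features:
        feature_names = ["mito_ribo_ratio", "clr_n_umi"] + score_cols
    model = classifier.fit_glm(feats, training, feature_names=feature_names, cutoff=cutoff)
    pred = classifier.predict_doublets(model, feats, training=training)
    report["n_training_positives"] = int(len(training.positives))
    report["n_predicted"] = int(pred["call"].sum())
    report["estimated_doublet_proportion"] = classifier.estimate_doublet_proportion(pred["call"])

    table = pd.DataFrame(
        {
            "sample_id": ds.rna.obs["sample_id"],
            "cluster": clusters,
            "cell_type": labels,
            "cite_flag": call_frame.get("cite", pd.Series(False, index=ds.barcodes)),
            "vdj_flag": call_frame.get("vdj", pd.Series(False, index=ds.barcodes)),
            "training": pred["training"],
            "probability": pred["probability"],
            "call": pred["call"],
        }
    )
    return {
        "calls": table,
        "model": model,
        "report": report,
        "features": feats,
        "cite_table": cite_table,
        "vdj_table": vdj_table,
        "training": training,
    }


def run_synthetic_benchmark(
    proportion: float,
    seed: int = 0,
    config: simulate.SynthConfig | None = None,
    sources=("vdj", "cite"),
    cutoff: float = 0.5,
    min_group: int = 5,
) -> dict:
    """Generate -> clean -> spike -> detect -> score against planted truth."""
    cfg = config or simulate.SynthConfig()
    base = simulate.generate_synthetic(cfg, seed=seed)
    base = simulate.clean_base(base)
    spiked, truth = simulate.spike_doublets(base, proportion, seed=seed + 1)
    result = detect_doublets(
        spiked,
        type_markers={t: g for t, g in simulate.DEFAULT_TYPE_MARKERS.items() if t in cfg.n_cells},
        adt_positive_types=cfg.adt_positive_types,
        exclusive_pairs=simulate.DEFAULT_SYNTH_PAIRS,
        sources=sources,
        cutoff=cutoff,
        seed=seed,
    )
    truth = truth.loc[truth.index.intersection(result["calls"].index)]
    sens_table, specificity = simulate.score_detection(
        result["calls"]["call"], truth, min_group=min_group
    )
    result["truth"] = truth
    result["sensitivity_table"] = sens_table
    result["specificity"] = specificity
    result["true_proportion"] = float(truth["is_doublet"].mean())
    result["estimated_proportion"] = result["report"]["estimated_doublet_proportion"]
    return result


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """File-based pipeline: read the inputs named in ``config``, detect, write.

    Config keys: ``expression`` (path), optional ``adt`` (CSV barcodes x
    antibodies), optional ``contigs`` (CSV), optional ``labels`` (TSV barcode,
    cell_type), ``type_markers``, ``adt_positive_types``, ``exclusive_pairs``,
    ``b_cell_types``/``t_cell_types``, ``sources``, ``cutoff``, ``qc``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "expression" not in config:
        raise ValueError("config must name an 'expression' input")
    for key in ("expression", "adt", "contigs", "labels"):
        if key in config and not Path(config[key]).exists():
            raise FileNotFoundError(f"{key} input not found: {config[key]}")

    rna = io.read_expression(config["expression"], sample_id=config.get("sample_id"))
    adt = (
        pd.read_csv(config["adt"], index_col=0)
        if "adt" in config
        else pd.DataFrame(index=rna.obs_names)
    )
    adt = adt.reindex(rna.obs_names).fillna(0).astype(int)
    contigs = (
        io.read_contigs(config["contigs"])
        if "contigs" in config
        else pd.DataFrame(columns=["barcode", "chain", "productive", "umis", "v_gene", "cdr3", "usable"])
    )
    labels = None
    if "labels" in config:
        lab = pd.read_csv(config["labels"], sep="\t", index_col=0)
        labels = lab.iloc[:, 0]

    dataset = simulate.MultiomicDataset(rna=rna, adt=adt, contigs=contigs)
    result = detect_doublets(
        dataset,
        labels=labels,
        type_markers=config.get("type_markers"),
        adt_positive_types=config.get("adt_positive_types"),
        exclusive_pairs=[tuple(p) for p in config["exclusive_pairs"]]
        if "exclusive_pairs" in config
        else None,
        b_cell_types=tuple(config.get("b_cell_types", ("B cell",))),
        t_cell_types=tuple(config.get("t_cell_types", ("T cell",))),
        sources=tuple(config.get("sources", ("vdj", "cite"))),
        cutoff=float(config.get("cutoff", 0.5)),
        seed=seed,
        qc_kwargs=config.get("qc"),
    )
    feats = result["features"].copy()
    try:
        from . import gmm

        fit = gmm.fit_gmm2(feats["mito_ribo_ratio"].to_numpy(), seed=seed)
        feats["dying_flag"] = gmm.flag_dying(feats, fit.threshold_)
        (out_dir / "mito_ribo_gmm.json").write_text(
            json.dumps(
                {
                    "weights": fit.weights_.tolist(),
                    "means": fit.means_.tolist(),
                    "variances": fit.variances_.tolist(),
                    "threshold": fit.threshold_,
                    "converged": fit.converged_,
                },
                indent=2,
            )
        )
    except ValueError as exc:  # unimodal / degenerate ratio distribution
        log.warning("mito-ribo GMM threshold unavailable: %s", exc)
    result["calls"].to_csv(out_dir / "doublet_calls.tsv", sep="\t")
    feats.to_csv(out_dir / "droplet_features.tsv", sep="\t")
    result["model"].to_json(out_dir / "model.json")
    report = dict(result["report"], seed=seed)
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return result
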