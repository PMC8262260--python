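"""VDJ contig filtering and the multiplet rule engine.

A droplet is a VDJ-identified doublet/multiplet if, on its retained contigs
(productive, >= 6 UMIs, recognised chain), any of the following fires:

a. it carries both a BCR chain (IGH and/or IGK/L) and a TCR chain (TRA and/or TRB);
b. it carries multiple BCRs: >= 2 IGH chains, or >= 2 light chains (IGK and IGL pooled);
c. it carries multiple TCRs: >= 2 TRB chains (>= 2 TRA only when ``count_dual_tra`` —
   off by default, since 1-10% of genuine T cells express two alpha chains);
d. it carries a BCR chain but does not co-cluster with B cells;
e. it carries a TCR chain but does not co-cluster with T cells.

Rules a/d/e mark heterotypic doublets; a droplet flagged only by b (or only by
c) is a homotypic BCR (TCR) doublet.
"""

from __future__ import annotations

import pandas as pd

BCR_HEAVY = {"IGH"}
BCR_LIGHT = {"IGK", "IGL"}
TCR_CHAINS = {"TRA", "TRB"}
BCR_CHAINS = BCR_HEAVY | BCR_LIGHT

RULESET = ("a", "b", "c", "d", "e")


def filter_contigs(contigs: pd.DataFrame, min_umis: int = 6) -> pd.DataFrame:
    """Retain productive contigs with >= min_umis UMIs on recognised chains.

    Identical (chain, v_gene, cdr3) duplicates on one barcode — a cell-ranger
    reporting artifact — are collapsed to the highest-UMI record before any
    chain counting.
    """
    usable = contigs["usable"] if "usable" in contigs else contigs["chain"].isin(
        BCR_CHAINS | TCR_CHAINS
    )
    kept = contigs[usable & contigs["productive"] & (contigs["umis"] >= min_umis)]
    kept = kept.sort_values("umis", ascending=False).drop_duplicates(
        subset=["barcode", "chain", "v_gene", "cdr3"], keep="first"
    )
    return kept.sort_index()


def _rules_for_barcode(
    chain_counts: dict[str, int],
    label: str | None,
    b_cell_types: frozenset,
    t_cell_types: frozenset,
    count_dual_tra: bool,
) -> set[str]:
    n_igh = chain_counts.get("IGH", 0)
    n_light = chain_counts.get("IGK", 0) + chain_counts.get("IGL", 0)
    n_tra = chain_counts.get("TRA", 0)
    n_trb = chain_counts.get("TRB", 0)
    n_bcr = n_igh + n_light
    n_tcr = n_tra + n_trb
    fired = set()
    if n_bcr >= 1 and n_tcr >= 1:
        fired.add("a")
    if n_igh >= 2 or n_light >= 2:
        fired.add("b")
    if n_trb >= 2 or (count_dual_tra and n_tra >= 2):
        fired.add("c")
    if label is not None:
        if n_bcr >= 1 and label not in b_cell_types:
            fired.add("d")
        if n_tcr >= 1 and label not in t_cell_types:
            fired.add("e")
    return fired


def _subtype(fired: set[str]) -> str:
    if not fired:
        return "none"
    if fired & {"a", "d", "e"}:
        return "heterotypic"
    if fired == {"b"}:
        return "homotypic_BCR"
    if fired == {"c"}:
        return "homotypic_TCR"
    return "heterotypic"  # b+c without a cannot occur; defensive


def identify_vdj_doublets(
    contigs: pd.DataFrame,
    labels: pd.Series | None = None,
    b_cell_types=("B cell",),
    t_cell_types=("T cell",),
    count_dual_tra: bool = False,
) -> pd.DataFrame:
    """Apply rules (a)-(e) per barcode on already-filtered contigs.

    ``labels`` maps barcode -> cell-type/cluster name; barcodes without a label
    skip the transcriptome-discordance rules d/e. Returns one row per barcode
    carrying contigs: ``flag``, ``rules`` (e.g. "a;e"), ``subtype``, ``n_umi_vdj``.
    """
    b_types = frozenset(b_cell_types)
    t_types = frozenset(t_cell_types)
    if labels is not None:
        known = set(labels.dropna().unique())
        unknown = (b_types | t_types) - known
        if unknown and len(known):
            raise ValueError(f"cell types {sorted(unknown)} not present in labels")
    rows = []
    for barcode, grp in contigs.groupby("barcode"):
        counts = grp["chain"].value_counts().to_dict()
        label = None
        if labels is not None and barcode in labels.index and pd.notna(labels[barcode]):
            label = labels[barcode]
        fired = _rules_for_barcode(counts, label, b_types, t_types, count_dual_tra)
        rows.append(
            {
                "barcode": barcode,
                "flag": bool(fired),
                "rules": ";".join(sorted(fired)),
                "subtype": _subtype(fired),
                "n_umi_vdj": int(grp["umis"].sum()),
            }
        )
    out = pd.DataFrame(rows, columns=["barcode", "flag", "rules", "subtype", "n_umi_vdj"])
    return out.set_index("barcode")
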