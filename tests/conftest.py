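import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from mltiplet.simulate import MultiomicDataset, SynthConfig, generate_synthetic


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_cells={"B cell": 200, "T cell": 260, "myeloid": 160}, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> MultiomicDataset:
    """~620-cell synthetic base dataset shared (read-only) across tests."""
    return generate_synthetic(small_config, seed=11)


def dataset_from_numi(numis, sample_ids=None) -> MultiomicDataset:
    """Minimal one-gene dataset whose per-droplet nUMI is exactly `numis`."""
    numis = np.asarray(numis)
    barcodes = [f"bc{i}" for i in range(len(numis))]
    obs = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else "S1",
            "cell_type_truth": "T cell",
            "apoptotic": False,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    rna = AnnData(X=numis[:, None].astype(float), obs=obs, var=pd.DataFrame(index=["G1"]))
    adt = pd.DataFrame({"CD3": 1}, index=obs.index)
    contigs = pd.DataFrame(
        columns=["barcode", "chain", "productive", "umis", "v_gene", "cdr3", "usable"]
    )
    return MultiomicDataset(rna=rna, adt=adt, contigs=contigs)


def contig_row(barcode, chain, productive=True, umis=10, v_gene="V1", cdr3="CASSF"):
    return {
        "barcode": barcode,
        "chain": chain,
        "productive": productive,
        "umis": umis,
        "v_gene": v_gene,
        "cdr3": cdr3,
        "usable": chain in {"IGH", "IGK", "IGL", "TRA", "TRB"},
    }
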