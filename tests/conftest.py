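import numpy as np
import pandas as pd
import pytest

from m6akit.io import CountMatrix, HierarchyTree, SampleSheet
from m6akit.nbtest import EnrichmentResult, benjamini_hochberg


@pytest.fixture
def chain_tree() -> HierarchyTree:
    return HierarchyTree(
        ["SSC", "pBCSP", "BCSP", "Thy"],
        [("SSC", "pBCSP"), ("pBCSP", "BCSP"), ("BCSP", "Thy")],
    )


@pytest.fixture
def small_counts() -> CountMatrix:
    return CountMatrix(
        ["G1", "G2", "G3"],
        ["S1", "S2"],
        np.array([[10, 20], [5, 10], [0, 0]]),
    )


@pytest.fixture
def sheet_8pop() -> SampleSheet:
    rows = []
    pops = ["SSC", "pBCSP", "BCSP", "PCP", "Thy", "BLSP", "6C3", "HEC"]
    for pop in pops:
        for assay in ("IP", "INPUT"):
            for rep in (1, 2):
                rows.append({"sample_id": f"{pop}_{assay}_{rep}", "population": pop,
                             "assay": assay, "condition": "WT", "replicate": rep})
    return SampleSheet(pd.DataFrame(rows))


def make_result(gene_ids, log2fc, p_value, wald_stat=None) -> EnrichmentResult:
    """Hand-build an EnrichmentResult table for threshold/landscape tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    wald = np.asarray(wald_stat, dtype=float) if wald_stat is not None else log2fc * 3.0
    table = pd.DataFrame({
        "gene_id": list(gene_ids),
        "base_mean": np.full(len(log2fc), 50.0),
        "log2fc": log2fc,
        "se": np.where(wald != 0, log2fc / np.where(wald == 0, 1, wald), 1.0),
        "wald_stat": wald,
        "p_value": p_value,
        "padj": benjamini_hochberg(p_value),
        "n_eff": 4,
        "flag": "",
    })
    return EnrichmentResult(table)
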