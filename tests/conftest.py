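import numpy as np
import pandas as pd
import pytest

from regustress.data_model import ContrastDesign, DEGTable, ExpressionStudy


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_study(values, genes=None, samples=None, conditions=None, strains=None,
               time_h=None, ethanol=None):
    """Build a small validated ExpressionStudy from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(1, n_genes + 1)]
    samples = samples or [f"s{i}" for i in range(1, n_samples + 1)]
    conditions = conditions or ["treatment"] * (n_samples // 2) + ["control"] * (
        n_samples - n_samples // 2
    )
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": list(range(1, n_samples + 1)),
            "strain": strains or ["synthetic"] * n_samples,
            "time_h": pd.array(time_h or [pd.NA] * n_samples, dtype="Int64"),
            "ethanol_pct": ethanol or [np.nan] * n_samples,
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionStudy(values=pd.DataFrame(values, index=genes, columns=samples), metadata=meta)


def make_deg_table(calls, contrast="c1", fold_changes=None):
    """DEGTable from a gene -> call mapping."""
    genes = list(calls)
    fc = fold_changes or {}
    default_fc = {"up": 2.0, "down": 0.5, "ns": 1.0, "not_expressed": np.nan}
    return DEGTable(
        pd.DataFrame(
            {
                "gene": genes,
                "contrast": contrast,
                "fold_change": [fc.get(g, default_fc[calls[g]]) for g in genes],
                "p_value": [np.nan if calls[g] == "not_expressed" else 0.01 for g in genes],
                "mean_rel_diff": np.nan,
                "call": [calls[g] for g in genes],
            }
        )
    )


@pytest.fixture
def balanced_contrast():
    return ContrastDesign(
        name="c1", treatment=("s1", "s2", "s3"), control=("s4", "s5", "s6"),
        ethanol_pct=5.0,
    )
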