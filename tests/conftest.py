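import numpy as np
import pandas as pd
import pytest

from senprof.expression import DEComparison, PopulationExpression
from senprof.synth import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    return generate_world(WorldConfig(), seed=1)


@pytest.fixture()
def small_expr():
    """2 populations x 3 replicates, 4 genes, TPM units."""
    genes = ["gA", "gB", "gC", "gD"]
    samples = [f"P1.Sen.3dpi.young.r{i}" for i in (1, 2, 3)] + [
        f"P1.NSen.3dpi.young.r{i}" for i in (1, 2, 3)
    ]
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(1, 100, size=(4, 6)), index=genes, columns=samples
    )
    ann = pd.DataFrame(
        {
            "cell_type": ["P1"] * 6,
            "state": ["Sen"] * 3 + ["NSen"] * 3,
            "timepoint": ["3dpi"] * 6,
            "age": ["young"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(samples, name="sample"),
    )
    lengths = pd.Series([1000, 2000, 1500, 500], index=genes)
    return PopulationExpression(values, ann, lengths, unit="tpm")


def make_de(rows: dict[str, tuple[float, float, float]], comparison="test") -> DEComparison:
    """DEComparison from {gene: (log2fc, pvalue, padj)}."""
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["log2fc", "pvalue", "padj"]
    )
    table.index.name = "gene"
    return DEComparison(comparison, table)


@pytest.fixture()
def de_factory():
    return make_de
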