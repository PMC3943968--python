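import numpy as np
import pandas as pd
import pytest

from csfpre.io import AbundanceMatrix, SampleMeta
from csfpre.synthetic_data import ProteinCatalog, SimulationSpec, generate_catalog


def make_catalog(rows: dict[str, dict]) -> ProteinCatalog:
    """Hand-built catalog; rows map accession -> column overrides."""
    defaults = {
        "origin": "cns",
        "c_csf": 1.0,
        "r_volume": 0.0,
        "cell_assoc_frac": 0.0,
        "payload_ratio": 0.0,
        "gradient_amp": 1.0,
        "depleted": False,
    }
    table = pd.DataFrame(
        {acc: {**defaults, **over} for acc, over in rows.items()}
    ).T
    table.index.name = "accession"
    for col in ("c_csf", "r_volume", "cell_assoc_frac", "payload_ratio", "gradient_amp"):
        table[col] = table[col].astype(float)
    return ProteinCatalog(table)


def make_matrix(values: dict[str, list[float]], meta: dict[str, SampleMeta],
                accessions: list[str] | None = None, peptide_counts=None) -> AbundanceMatrix:
    n = len(next(iter(values.values())))
    idx = accessions or [f"P{i}" for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index(idx, name="accession"))
    return AbundanceMatrix(df, meta, peptide_counts)


@pytest.fixture
def noise_free_spec() -> SimulationSpec:
    return SimulationSpec(seed=7, noise_cv=0.0)


@pytest.fixture
def noise_free_catalog(noise_free_spec) -> ProteinCatalog:
    return generate_catalog(noise_free_spec)
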