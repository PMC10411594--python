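import numpy as np
import pandas as pd
import pytest

from asecross import AnalysisConfig, AseCountTable
from asecross.core_io import Scope


@pytest.fixture
def acfg() -> AnalysisConfig:
    return AnalysisConfig()


def build_table(counts_by_sample: dict[str, tuple[float, float]],
                directions: dict[str, str] | None = None,
                n_genes: int = 1,
                sex: str = "F", tissue: str = "head") -> AseCountTable:
    """One-scope table: every gene gets the same (A, B) counts per sample."""
    directions = directions or {}
    cols = {}
    meta_rows = []
    for i, (sid, (a, b)) in enumerate(counts_by_sample.items()):
        cols[f"{sid}.A"] = [a] * n_genes
        cols[f"{sid}.B"] = [b] * n_genes
        meta_rows.append(
            {
                "sample_id": sid,
                "cross_id": "c1",
                "direction": directions.get(sid, "AxB" if i % 2 == 0 else "BxA"),
                "sex": sex,
                "tissue": tissue,
                "replicate": i // 2 + 1,
                "library_size": 0.0,
            }
        )
    counts = pd.DataFrame(cols, index=[f"g{i+1}" for i in range(n_genes)])
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return AseCountTable(counts=counts, meta=meta)


@pytest.fixture
def scope_f_head() -> Scope:
    return Scope(sex="F", tissue="head", cross_id="c1")


@pytest.fixture
def balanced_table() -> AseCountTable:
    """4 samples (2 per direction), all observations equal: the null design."""
    return build_table(
        {"s1": (100, 100), "s2": (100, 100), "s3": (100, 100), "s4": (100, 100)},
        directions={"s1": "AxB", "s2": "BxA", "s3": "AxB", "s4": "BxA"},
    )
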