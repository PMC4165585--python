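import numpy as np
import pandas as pd
import pytest

from methpanel.candidate_selection import ExpressionMatrix
from methpanel.synthio import SimulationConfig


@pytest.fixture
def small_sim_config():
    """Fast config: few genes, tiny cohort."""
    return SimulationConfig(
        seed=11,
        n_genes=12,
        n_candidate_genes=3,
        groups=(
            ("control:Bcell", 5, "test"),
            ("BL", 4, "test"),
            ("ABC", 4, "test"),
            ("GCB", 3, "validation"),
            ("FL", 3, "validation"),
        ),
        methylation_frequency={
            "GA": {"BL": 1.0, "ABC": 0.5, "GCB": 0.5, "FL": 0.0},
            "GB": {"BL": 0.0, "ABC": 1.0, "GCB": 1.0, "FL": 1.0},
        },
        n_patients_per_type=3,
    )


def build_expression(values, meta_rows):
    """Assemble an ExpressionMatrix from a dict gene -> {sample: value} and
    metadata row tuples (sample, type, origin, cell_line, treatment)."""
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "lymphoma_type", "origin", "cell_line", "treatment"],
    )
    df = pd.DataFrame(values).T
    df = df[meta["sample"].tolist()]
    return ExpressionMatrix(df, meta)


@pytest.fixture
def paired_meta_rows():
    """Two types, two cell lines each (treated/untreated), two patients each."""
    rows = []
    for t in ("BL", "FL"):
        for i in (1, 2):
            line = f"{t}_cl{i}"
            rows.append((f"{line}_untreated", t, "cell_line", line, "untreated"))
            rows.append((f"{line}_treated", t, "cell_line", line, "treated"))
        for i in (1, 2):
            rows.append((f"{t}_pt{i}", t, "patient", "n/a", "n/a"))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)
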