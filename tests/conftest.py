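import numpy as np
import pandas as pd
import pytest

from xcmap import ExpressionMatrix, default_design, generate_cohort


def make_matrix(values: dict[str, list[float]], genes: list[str], **anno) -> ExpressionMatrix:
    """Small ExpressionMatrix; annotation defaults are filled per sample."""
    df = pd.DataFrame(values, index=genes, dtype=float)
    samples = list(df.columns)
    base = {
        "subset": anno.get("subset", ["s"] * len(samples)),
        "tissue": anno.get("tissue", ["blood"] * len(samples)),
        "species": anno.get("species", ["human"] * len(samples)),
        "donor": anno.get("donor", [f"d{i}" for i in range(len(samples))]),
    }
    annotations = pd.DataFrame(base, index=samples)
    return ExpressionMatrix(df, annotations)


@pytest.fixture(scope="session")
def default_cohort():
    """One default two-species cohort shared across tests (seed fixed)."""
    matrices, table, truth = generate_cohort(default_design(seed=1))
    return matrices, table, truth


@pytest.fixture(scope="session")
def no_signal_cohort():
    """Cohort without lineage or tissue effects: pure noise plus donor shifts."""
    design = default_design(seed=11, lineage_effect=0.0, tissue_effect=0.0)
    matrices, table, truth = generate_cohort(design)
    return matrices, table, truth
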