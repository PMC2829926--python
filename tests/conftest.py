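import numpy as np
import pandas as pd
import pytest

from traitsig.study import ExpressionStudy


def make_study(
    values,
    detected=None,
    weight_loss=None,
    crp=None,
    gene_ids=None,
    sample_ids=None,
) -> ExpressionStudy:
    """Build a small ExpressionStudy from raw arrays with sensible defaults."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if detected is None:
        detected = np.ones_like(values, dtype=bool)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samples)]
    if weight_loss is None:
        weight_loss = np.linspace(0, 20, n_samples)
    if crp is None:
        crp = np.full(n_samples, 3.0)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "weight_loss_pct": np.asarray(weight_loss, dtype=float),
            "bmi": np.full(n_samples, 25.0),
            "crp": np.asarray(crp, dtype=float),
        }
    )
    return ExpressionStudy(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        detected=np.asarray(detected, dtype=bool),
        clinical=clinical,
    )


@pytest.fixture
def toy_study():
    rng = np.random.default_rng(42)
    return make_study(rng.normal(7, 1, size=(20, 8)))
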