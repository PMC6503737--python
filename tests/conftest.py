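import numpy as np
import pandas as pd
import pytest

from omnimeta.datatypes import ExpressionStudy, SyntheticConfig
from omnimeta.syndata import generate_collection


def make_study(G=50, n_case=5, n_control=5, seed=0, study_id="S1",
               shift=None):
    """Small random study; ``shift`` adds a constant to the case arm of
    the first len(shift) genes."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(G)]
    samples = [f"{study_id}_s{j}" for j in range(n_case + n_control)]
    X = rng.normal(7, 1.5, size=(G, 1)) + rng.normal(0, 1, size=(G, len(samples)))
    group = pd.Series(["control"] * n_control + ["case"] * n_case,
                      index=samples)
    if shift is not None:
        X[: len(shift), n_control:] += np.asarray(shift)[:, None]
    return ExpressionStudy(
        study_id=study_id,
        expr=pd.DataFrame(X, index=genes, columns=samples),
        group=group,
    )


@pytest.fixture
def null_study():
    return make_study(G=200, n_case=6, n_control=6, seed=11)


@pytest.fixture(scope="session")
def hsr_collection():
    """HS_r collection with planted signal, shared across tests."""
    config = SyntheticConfig(K=5, G=500, n_case=12, n_control=12,
                             pi_de=0.1, scenario="HS_r", r_frac=0.8,
                             mu=1.2, tau2=0.05, seed=21)
    return generate_collection(config)
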