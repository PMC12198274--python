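import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from modnet.datasets import ITEMS, SymptomDataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """Tiny ground truth with a few base edges and one planted moderation."""
    from modnet.synthetic import GroundTruthNetworks

    return GroundTruthNetworks.from_base(
        edges=[("seat", "run", 0.3), ("closeatt", "susatt", 0.3), ("run", "motor", 0.2)],
        moderated_edges=[("run", "motor", "ADHD-stim", 0.25)],
    )


@pytest.fixture(scope="session")
def default_truth():
    from modnet.synthetic import default_ground_truth

    return default_ground_truth()


@pytest.fixture()
def tiny_dataset():
    """40-participant two-group dataset with deterministic random scores."""
    rng = np.random.default_rng(7)
    scores = rng.integers(0, 4, (40, 18)).astype(float)
    idx = [f"p{i:03d}" for i in range(40)]
    items = pd.DataFrame(scores, columns=list(ITEMS), index=idx)
    groups = pd.Series(["NAC"] * 20 + ["ADHD-stim"] * 20, index=idx)
    covs = pd.DataFrame(
        {
            "age": rng.uniform(8, 25, 40).round(1),
            "sex": rng.integers(0, 2, 40),
            "site": rng.choice(["amsterdam", "nijmegen"], 40),
        },
        index=idx,
    )
    return SymptomDataset(items=items, groups=groups, covariates=covs)
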