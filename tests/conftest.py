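import numpy as np
import pytest

from funcsfa import (MultiOmicsDataset, OmicsMatrix, SyntheticSpec,
                     generate_dataset, scale_by_datatype_sd)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dataset(rng, n_samples=6, block_sizes=(4, 3), labels=None):
    """Tiny dense dataset for oracle tests (N, n <= 10)."""
    labels = labels or [f"t{i}" for i in range(len(block_sizes))]
    samples = [f"S{i}" for i in range(n_samples)]
    blocks = [
        OmicsMatrix(rng.standard_normal((n_samples, n)), samples,
                    [f"{lab}_f{j}" for j in range(n)], lab)
        for lab, n in zip(labels, block_sizes)
    ]
    return MultiOmicsDataset(blocks)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def recovery_case():
    """The canonical recovery fixture: N=300, k=4, n=(500,60,40),
    s=(0.2,0.5,0.5), tau=1, SNR 3:1."""
    spec = SyntheticSpec(seed=1)
    dataset, Z, B = generate_dataset(spec)
    scaled, _ = scale_by_datatype_sd(dataset)
    return spec, scaled, Z, B
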