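import numpy as np
import pytest

from tla_unet import PhantomSpec, generate_phantom_dataset, smoke_benchmark, train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """16 small, quick phantoms shared by pipeline-level tests."""
    spec = PhantomSpec(n_samples=16, image_size=32, n_structures=2, seed=11)
    return generate_phantom_dataset(spec)


@pytest.fixture(scope="session")
def smoke_runs():
    """Two identical runs of the standard learning benchmark (seed 0).

    Shared by the learning, reproducibility and ablation checks so the
    expensive training happens once per session.
    """
    spec, model_cfg, train_cfg = smoke_benchmark(seed=0)
    dataset = generate_phantom_dataset(spec)
    first = train(model_cfg, train_cfg, dataset)
    second = train(model_cfg, train_cfg, dataset)
    return first, second
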