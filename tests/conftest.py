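import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest config exercising every architectural element."""
    from mcldti.network import ModelConfig

    return ModelConfig(h=16, d_model=8, n_heads=2, L_drug=8, L_tgt=16,
                       mlp_ratio=2.0, fusion_hidden=16, dropout=0.1,
                       conv_channels=(4, 4, 8, 8))


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 synthetic pairs with short proteins, both classes present."""
    from mcldti.synthetic import SyntheticSpec, gen_dataset

    spec = SyntheticSpec(n_examples=16, seed=5, protein_length=(10, 16))
    return gen_dataset(spec)


@pytest.fixture
def float64_engine(monkeypatch):
    """Run the autograd engine in float64 for numerical gradient checks."""
    import mcldti.nn.autograd as ag

    monkeypatch.setattr(ag, "DTYPE", np.float64)
    yield


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar-valued f() w.r.t. array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
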