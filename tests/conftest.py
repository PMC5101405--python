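import numpy as np
import pytest

from cdbntrack import crbm, synthdata
from cdbntrack.cdbn import CDBNClassifier
from cdbntrack.crbm import standardize_patch


@pytest.fixture(scope="session")
def pretrained_reduced():
    """Reduced-preset CDBN pretrained on the synthetic 10-class set."""
    X, y = synthdata.make_class_dataset(50, seed=2, channels=1)
    model = CDBNClassifier(architecture="reduced", crbm_epochs=30,
                           head_epochs=600, random_state=0)
    model.fit(X, y)
    return model, X, y


@pytest.fixture(scope="session")
def patch_dataset():
    """Small labeled patch set shared across training tests."""
    X, y = synthdata.make_class_dataset(20, seed=1, channels=1)
    return X, y


@pytest.fixture(scope="session")
def standardized_patches(patch_dataset):
    X, _ = patch_dataset
    return np.stack([standardize_patch(p)[0] for p in X])


@pytest.fixture()
def small_layer():
    rng = np.random.default_rng(7)
    layer = crbm.init_layer(1, 3, 1, 2, 0.1, weight_scale=0.5, rng=rng)
    layer.hidden_bias[:] = rng.normal(0.0, 0.5, 1)
    layer.visible_bias = 0.3
    return layer


TINY_ARCH = dict(
    layers=[
        dict(n_filters=2, filter_size=5, pool_size=2, sparsity_target=0.02),
        dict(n_filters=3, filter_size=3, pool_size=2, sparsity_target=0.02),
    ],
    fc_units=4,
    n_out=1,
)


@pytest.fixture()
def tiny_model():
    """12x12-input two-layer CDBN with a one-unit head, randomly built."""
    return CDBNClassifier(architecture=TINY_ARCH, input_size=12, channels=1,
                          weight_scale=0.3, random_state=3).build()
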