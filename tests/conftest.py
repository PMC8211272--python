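import numpy as np
import pytest

from dnv1.core import DNParams, SubunitParams
from dnv1.model import Architecture, EncodingModel
from dnv1.readout import ReadoutParams, TentGrid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def finite_difference_gradients(f, arrays, eps=1e-6):
    """Central finite differences of a scalar-valued Tensor function."""
    from dnv1.autodiff import Tensor
    grads = []
    for j, a in enumerate(arrays):
        num = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            ap, am = a.copy(), a.copy()
            ap[i] += eps
            am[i] -= eps
            args_p = [ap if k == j else arrays[k] for k in range(len(arrays))]
            args_m = [am if k == j else arrays[k] for k in range(len(arrays))]
            num[i] = (f(*[Tensor(x) for x in args_p]).data
                      - f(*[Tensor(x) for x in args_m]).data) / (2 * eps)
        grads.append(num)
    return grads


@pytest.fixture(scope="session")
def recovery_population_k1():
    """Synthetic population from an orientation-specific (kappa = 1)
    ground-truth DN model: 4000 images, 2 trials, 20 neurons."""
    from dnv1.synth import SyntheticConfig, make_dataset
    cfg = SyntheticConfig(n_images=4000, trials=(2, 2), kappa=1.0, seed=0)
    data, truth = make_dataset(cfg)
    return cfg, data, truth


@pytest.fixture()
def tiny_dn_model(rng):
    """Small random DN model (4 channels, 12 px images, 2 neurons)."""
    C, k, side = 4, 5, 12
    fs = side - k + 1
    filters = rng.normal(scale=0.3, size=(C, k, k))
    subunit = SubunitParams(filters, rng.normal(scale=0.1, size=C), use_bn=False)
    dn = DNParams(rng.uniform(0.8, 1.5, C), rng.uniform(0.5, 1.5, C),
                  rng.uniform(0, 0.5, (C, C)), pool_size=3)
    N = 2
    readout = ReadoutParams(rng.uniform(0, 0.2, (N, fs, fs)),
                            rng.uniform(0, 0.5, (N, C)),
                            rng.normal(scale=0.1, size=N),
                            rng.normal(scale=0.1, size=(N, len(TentGrid()))))
    arch = Architecture(channels=C, kernel_size=k, pool_size=3, variant="dn",
                        use_bn=False, n_neurons=N)
    return EncodingModel(arch, subunit, dn, readout), side
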