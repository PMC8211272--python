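"""Random initialization of trainable encoding models.

Filters start from a truncated normal (std 0.01), normalization weights
uniform on [0, 0.01], semi-saturation constants at 1 and exponents at 1
(so the DN stage starts near a gentle contrast normalization), readout
weights uniform positive and small, biases at 0 and the output
nonlinearity at the identity-like alpha = 0 its regularizer prefers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import DNParams, ExtendedDNParams, SubunitParams
from .model import Architecture, EncodingModel
from .readout import ReadoutParams, TentGrid

__all__ = ["init_model"]


def init_model(arch: Architecture, seed: int = 0,
               subunit: SubunitParams | None = None) -> EncodingModel:
    """Build a freshly initialized model of the given architecture.

    ``subunit`` may supply fixed first-stage filters (e.g. ground-truth
    filters for a frozen-core fit); otherwise filters are drawn from a
    truncated normal with std 0.01.
    """
    rng = np.random.default_rng(seed)
    C, k = arch.channels, arch.kernel_size
    if subunit is None:
        tn = stats.truncnorm(-2, 2, loc=0.0, scale=0.01)
        filters = tn.rvs(size=(C, k, k), random_state=rng)
        subunit = SubunitParams(filters, np.zeros(C), use_bn=arch.use_bn)

    dn = None
    if arch.variant in ("dn", "dn_nonspecific"):
        p = rng.uniform(0, 0.01, size=(C, C))
        if arch.variant == "dn_nonspecific":
            from .core import nonspecific_project
            p = nonspecific_project(p)
        dn = DNParams(np.ones(C), np.ones(C), p, pool_size=arch.pool_size)
    elif arch.variant == "dn_extended":
        kk = arch.norm_kernel_size
        dn = ExtendedDNParams(np.ones(C), np.ones(C),
                              rng.uniform(0, 0.1, size=(C, kk, kk, 2)),
                              rng.uniform(0, 0.1, size=(C, C, 2)),
                              kernel_size=kk, dilation=arch.dilation,
                              pool_size=arch.pool_size)

    fs = arch.feature_side
    N = arch.n_neurons
    readout = ReadoutParams(
        spatial=rng.uniform(0, 0.01, size=(N, fs, fs)),
        feature=rng.uniform(0, 0.1, size=(N, C)),
        bias=np.zeros(N),
        alpha=np.zeros((N, len(TentGrid()))),
    )
    return EncodingModel(arch, subunit, dn, readout)
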