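"""Complete encoding model: core variant + readout, with checkpointing.

An :class:`EncodingModel` bundles the subunit stage, one of the four
normalization variants and the per-neuron readout, and provides batched
spike-count prediction plus a portable on-disk format (one ``.npz`` array
container with one named array per parameter symbol, and a JSON sidecar
holding the architecture).

For the spatially-extended variant the input images must be larger than
40 px so that, after the valid first convolution and the dilated
normalization convolution, the shared feature space keeps the standard
28 px spatial size read by every readout: side = 40 + dilation*(k-1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .core import (DNParams, ExtendedDNParams, SubunitParams, dn_forward,
                   extended_dn_forward, subunit_forward, subunit_variant)
from .readout import ReadoutParams, TentGrid, output_nonlinearity, readout_forward

__all__ = ["Architecture", "EncodingModel", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1

VARIANTS = ("subunit", "dn", "dn_nonspecific", "dn_extended")


@dataclass
class Architecture:
    """Structural configuration shared by all model variants."""

    channels: int = 32
    kernel_size: int = 13
    pool_size: int = 5
    variant: str = "dn"
    norm_kernel_size: int = 1   # dn_extended only
    dilation: int = 5           # dn_extended only
    use_bn: bool = True
    n_neurons: int = 1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def image_side(self) -> int:
        """Required stimulus side for a 28 px shared feature space."""
        base = 40
        if self.variant == "dn_extended":
            base += self.dilation * (self.norm_kernel_size - 1)
        return base

    @property
    def feature_side(self) -> int:
        return 40 - self.kernel_size + 1   # 28 at the default kernel


class EncodingModel:
    """Subunit core + normalization variant + factorized readout."""

    def __init__(self, arch: Architecture, subunit: SubunitParams,
                 dn: DNParams | ExtendedDNParams | None,
                 readout: ReadoutParams):
        if arch.variant == "subunit" and dn is not None:
            raise ValueError("subunit variant carries no normalization parameters")
        if arch.variant in ("dn", "dn_nonspecific") and not isinstance(dn, DNParams):
            raise ValueError(f"variant {arch.variant!r} requires DNParams")
        if arch.variant == "dn_extended" and not isinstance(dn, ExtendedDNParams):
            raise ValueError("dn_extended requires ExtendedDNParams")
        self.arch = arch
        self.subunit = subunit
        self.dn = dn
        self.readout = readout

    # -- forward -------------------------------------------------------
    def core_forward(self, images, mode: str = "eval",
                     tensors: dict[str, Tensor] | None = None,
                     driving: Tensor | None = None,
                     log_driving: Tensor | None = None) -> Tensor:
        """Shared feature maps z. ``driving`` (or its precomputed
        eps-shifted log, for the center DN path) may supply the subunit
        outputs directly, e.g. when the filters are frozen."""
        t = tensors or {}
        if driving is None and log_driving is None:
            driving = subunit_forward(images, self.subunit, mode=mode,
                                      filters=t.get("w"), biases=t.get("o"))
        if self.arch.variant == "subunit":
            return subunit_variant(driving)
        if self.arch.variant == "dn_extended":
            return extended_dn_forward(driving, self.dn, tensors=t)
        return dn_forward(driving, self.dn, tensors=t, log_driving=log_driving)

    def forward(self, images, mode: str = "eval",
                tensors: dict[str, Tensor] | None = None,
                driving: Tensor | None = None,
                log_driving: Tensor | None = None) -> Tensor:
        """Predicted mean spike counts rhat (B, N) as a graph Tensor."""
        t = tensors or {}
        z = self.core_forward(images, mode=mode, tensors=t, driving=driving,
                              log_driving=log_driving)
        g = readout_forward(z, self.readout, tensors=t)
        alpha = t.get("alpha")
        if alpha is None:
            alpha = self.readout.alpha
        return output_nonlinearity(g, alpha, self.readout.grid)

    def _cast_tensors(self, dtype) -> dict[str, Tensor]:
        arrays = {"w": self.subunit.filters, "o": self.subunit.biases,
                  "a": self.readout.spatial, "b": self.readout.feature,
                  "q": self.readout.bias, "alpha": self.readout.alpha}
        if isinstance(self.dn, DNParams):
            arrays.update(n=self.dn.exponents, sigma=self.dn.semi_saturation,
                          p=self.dn.norm_weights)
        elif isinstance(self.dn, ExtendedDNParams):
            arrays.update(n=self.dn.exponents, sigma=self.dn.semi_saturation,
                          c=self.dn.spatial_pools, d=self.dn.feature_weights)
        return {k: Tensor(np.asarray(v, dtype=dtype)) for k, v in arrays.items()}

    def predict(self, images, batch_size: int = 256,
                dtype=np.float32) -> np.ndarray:
        """Mean spike counts for a stack of images, evaluated in batches
        (single precision by default; pass ``dtype=np.float64`` for
        reference-accuracy predictions)."""
        images = np.asarray(images, dtype=dtype)
        tensors = self._cast_tensors(dtype)
        out = []
        for i in range(0, images.shape[0], batch_size):
            out.append(self.forward(images[i:i + batch_size],
                                    tensors=tensors).data)
        return np.concatenate(out, axis=0).astype(np.float64)

    # -- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {
            "w": self.subunit.filters, "o": self.subunit.biases,
            "a": self.readout.spatial, "b": self.readout.feature,
            "q": self.readout.bias, "alpha": self.readout.alpha,
        }
        if self.subunit.bn_mean is not None:
            arrays["bn_mean"] = self.subunit.bn_mean
            arrays["bn_var"] = self.subunit.bn_var
        if isinstance(self.dn, DNParams):
            arrays.update(n=self.dn.exponents, sigma=self.dn.semi_saturation,
                          p=self.dn.norm_weights)
        elif isinstance(self.dn, ExtendedDNParams):
            arrays.update(n=self.dn.exponents, sigma=self.dn.semi_saturation,
                          c=self.dn.spatial_pools, d=self.dn.feature_weights)
        np.savez(path, **arrays)
        sidecar = {"version": CHECKPOINT_VERSION, "architecture": asdict(self.arch),
                   "grid": asdict(self.readout.grid)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path, variant: str | None = None) -> "EncodingModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if sidecar.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {sidecar.get('version')}")
        arch = Architecture(**sidecar["architecture"])
        if variant is not None and arch.variant != variant:
            raise ValueError(
                f"checkpoint holds a {arch.variant!r} model, not {variant!r}")
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        subunit = SubunitParams(arrays["w"], arrays["o"], use_bn=arch.use_bn,
                                bn_mean=arrays.get("bn_mean"),
                                bn_var=arrays.get("bn_var"))
        dn = None
        if arch.variant in ("dn", "dn_nonspecific"):
            dn = DNParams(arrays["n"], arrays["sigma"], arrays["p"],
                          pool_size=arch.pool_size)
        elif arch.variant == "dn_extended":
            dn = ExtendedDNParams(arrays["n"], arrays["sigma"], arrays["c"],
                                  arrays["d"], kernel_size=arch.norm_kernel_size,
                                  dilation=arch.dilation, pool_size=arch.pool_size)
        grid = TentGrid(**sidecar["grid"])
        readout = ReadoutParams(arrays["a"], arrays["b"], arrays["q"],
                                arrays["alpha"], grid=grid)
        return cls(arch, subunit, dn, readout)
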