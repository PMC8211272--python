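"""Stimulus geometry: pixel/degree conversion and receptive-field coverage.

The recordings this package models were made at a fixed retinal scale of
35 px per degree of visual angle (2 degrees = 140 px originals, downsampled
by two, i.e. 70 px per degree halved to 35). All coverage numbers reported
by the models — how much of the visual field a convolution kernel, the
denominator pooling window, or a dilated normalization pool "sees" — are
pure functions of the architecture constants collected in
:class:`GeometryConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GeometryConfig", "px_to_deg", "coverage_extent"]


@dataclass(frozen=True)
class GeometryConfig:
    """Fixed retinal/architectural geometry of the encoding model.

    Attributes
    ----------
    px_per_deg:
        Pixels per degree of visual angle after preprocessing (35).
    image_side:
        Side of the model input, px (40, i.e. 1.14 deg).
    conv_kernel:
        Side of the first-layer convolution kernel, px (13, i.e. 0.37 deg).
    pool:
        Side of the average-pooling window applied to the exponentiated
        feature maps inside the normalization denominator, px (5).
    dilation:
        Dilation factor of the spatially-extended normalization
        convolution (5; one kernel tap per 5x5 pool).
    """

    px_per_deg: float = 35.0
    image_side: int = 40
    conv_kernel: int = 13
    pool: int = 5
    dilation: int = 5


def px_to_deg(px: float, geometry: GeometryConfig = GeometryConfig(),
              round_to: int | None = None) -> float:
    """Convert a pixel extent to degrees of visual angle.

    ``round_to=2`` gives the two-decimal convention used in reports
    (40 px -> 1.14 deg, 28 px -> 0.80 deg); by default full precision
    is returned.
    """
    if px < 0:
        raise ValueError("pixel extent must be non-negative")
    deg = px / geometry.px_per_deg
    return round(deg, round_to) if round_to is not None else deg


def coverage_extent(kind: str, geometry: GeometryConfig = GeometryConfig(),
                    kernel_size: int | None = None) -> tuple[int, int, float]:
    """Spatial extent covered by a model stage.

    Parameters
    ----------
    kind:
        ``"conv"`` — the first convolution kernel itself;
        ``"pool"`` — the 5 px denominator pooling window, traced back
        through the first convolution to the input image;
        ``"dn_pool"`` — a dilated normalization kernel of odd side
        ``kernel_size``, whose taps each aggregate one pooling window,
        traced back to the input image.
    kernel_size:
        Normalization kernel side for ``kind="dn_pool"`` (odd).

    Returns
    -------
    (feature_px, input_px, input_deg)
        Extent in the feature space, the corresponding extent in the
        input image (valid-convolution arithmetic: a feature extent of
        ``e`` sees ``e + conv_kernel - 1`` input pixels), and the input
        extent in degrees of visual angle rounded to two decimals.

    Notes
    -----
    With dilation equal to the pool size, a kernel of side ``k`` covers
    ``dilation*(k-1) + 1 + (pool-1) = 5k`` feature pixels: neighbouring
    taps pool from windows with coinciding boundaries. Hence a 3x3
    normalization kernel spans 15 px of feature space and
    ``15 + 13 - 1 = 27`` px (0.77 deg) of the input image.
    """
    g = geometry
    if kind == "conv":
        feature = g.conv_kernel
        input_px = g.conv_kernel
    elif kind == "pool":
        feature = g.pool
        input_px = g.pool + g.conv_kernel - 1
    elif kind == "dn_pool":
        if kernel_size is None:
            raise ValueError("dn_pool requires kernel_size")
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("normalization kernel side must be odd and positive")
        feature = g.dilation * (kernel_size - 1) + 1 + (g.pool - 1)
        input_px = feature + g.conv_kernel - 1
    else:
        raise ValueError(f"unknown coverage kind: {kind!r}")
    return feature, input_px, px_to_deg(input_px, g, round_to=2)
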