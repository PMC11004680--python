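"""Multilevel guided edge-preserving (MLGEPF) decomposition.

One gray image is split into seven additive layers: three small-scale
components SC(1..3), three large-scale components LC(1..3), and one
background component BC.  At level i with running base I_{i-1} (I_0 = the
image):

    g_i = guided_filter(I_{i-1}, guidance = I_{i-1} - |grad I_{i-1}|)
    h_i = gaussian_blur(I_{i-1}, sigma_i)
    SC(i) = I_{i-1} - g_i          # fine texture the edge-preserving filter removes
    LC(i) = g_i - h_i              # edges the guided filter keeps but the Gaussian blurs away
    I_i   = h_i                    # the Gaussian chain carries the base to the next level
    BC    = I_levels

The guidance image is refreshed from each level's own input, so the
edge-preserving split adapts as the base coarsens.  The arrangement
telescopes — I_{i-1} = SC(i) + LC(i) + I_i — so the seven layers sum back
to the input exactly (to float rounding), for any filter parameters.
Layers are stored signed and never clipped; clipping would break the
additive reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DimensionError
from .filters import GuidedFilterParams, gaussian_blur, guided_filter, modified_guidance

__all__ = ["LayerStack", "DEFAULT_SIGMAS", "mlgepf_decompose", "recompose"]

#: Gaussian scale per level doubles so level 1 captures fine texture and
#: level 3 coarse structure.
DEFAULT_SIGMAS: tuple[float, ...] = (2.0, 4.0, 8.0)


@dataclass
class LayerStack:
    """The seven sublayers of one image; ``sc`` and ``lc`` are signed."""

    sc: list[np.ndarray]
    lc: list[np.ndarray]
    bc: np.ndarray
    source_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source_shape is None:
            self.source_shape = self.bc.shape
        if len(self.sc) != len(self.lc):
            raise DimensionError(
                f"sc/lc level counts differ: {len(self.sc)} vs {len(self.lc)}"
            )
        for layer in (*self.sc, *self.lc, self.bc):
            if layer.shape != tuple(self.source_shape):
                raise DimensionError(
                    f"layer shape {layer.shape} != source shape {self.source_shape}"
                )

    @property
    def levels(self) -> int:
        return len(self.sc)


def mlgepf_decompose(
    img: np.ndarray,
    levels: int = 3,
    gp: GuidedFilterParams = GuidedFilterParams(),
    sigmas: Sequence[float] = DEFAULT_SIGMAS,
) -> LayerStack:
    """Decompose ``img`` into ``levels`` pairs of SC/LC layers plus BC.

    ``sigmas`` gives the Gaussian scale of each level and must have length
    ``levels``.  The default three-level configuration yields the
    seven-layer split.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise DimensionError(f"need a 2-D image, got {img.ndim}-D")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if len(sigmas) != levels:
        raise ValueError(f"len(sigmas)={len(sigmas)} must equal levels={levels}")
    sc: list[np.ndarray] = []
    lc: list[np.ndarray] = []
    base = img
    for sigma in sigmas:
        g = guided_filter(base, modified_guidance(base), gp)
        h = gaussian_blur(base, sigma)
        sc.append(base - g)
        lc.append(g - h)
        base = h
    return LayerStack(sc=sc, lc=lc, bc=base, source_shape=img.shape)


def recompose(stack: LayerStack) -> np.ndarray:
    """Elementwise sum of all layers — the exact inverse of
    :func:`mlgepf_decompose` (to float rounding)."""
    out = stack.bc.copy()
    for layer in (*stack.sc, *stack.lc):
        out += layer
    return out
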