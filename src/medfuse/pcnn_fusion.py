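"""Structure-tensor PCNN (ST-PCNN) fusion of detail layers.

A pulse-coupled neural network assigns one spiking neuron to every pixel.
Each neuron receives its pixel value as feeding input F, accumulates a
linking field L from the recent pulses of its 8 neighbours, and fires when
its internal activity U = F (1 + beta L) crosses a decaying threshold theta;
firing kicks the threshold up so strong stimuli pulse repeatedly while weak
ones stay quiet.  The linking strength beta is not a constant here: it is a
structure-tensor saliency map — the layer's gradient magnitude rescaled to
[0, 1] — so edge and corner pixels couple more strongly and pulse sooner.

Two networks with identical schedules run side by side, one per modality,
and each records a firing-time map T (the iteration of the most recent
pulse, 0 = never fired).  Fusion is winner-take-all: the fused detail layer
copies, per pixel, whichever source layer's neuron fired more recently, with
the structural (MRI-slot) layer winning ties.  No averaging: every fused
pixel equals one of the two inputs at that pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import DimensionError
from .filters import gradient_magnitude

__all__ = [
    "PcnnParams",
    "DEFAULT_LINKING_KERNEL",
    "sts",
    "normalize_feed",
    "pcnn_firing_times",
    "fuse_layer",
]

#: Synaptic weights to the 8 neighbours; zero centre (no self-linking),
#: diagonal neighbours at half weight.
DEFAULT_LINKING_KERNEL: tuple[tuple[float, ...], ...] = (
    (0.5, 1.0, 0.5),
    (1.0, 0.0, 1.0),
    (0.5, 1.0, 0.5),
)


@dataclass(frozen=True)
class PcnnParams:
    """Constants of the simplified PCNN.

    iterations
        Simulation horizon n_max.
    alpha_theta, v_theta
        Threshold decay rate and the boost added on firing.  With
        v_theta >> 1 a neuron enters a long refractory period after each
        pulse, so the firing-time map separates stimulus strengths cleanly.
    alpha_l, v_l
        Linking-field decay rate and gain on neighbour pulses.
    linking_kernel
        3x3 nonnegative synaptic weights with zero centre.
    theta_init
        Initial threshold; feeds are normalized to [0, 1] so 1.0 means only
        full-scale pixels can fire at the first step.
    """

    iterations: int = 110
    alpha_theta: float = 0.2
    v_theta: float = 20.0
    alpha_l: float = 1.0
    v_l: float = 1.0
    theta_init: float = 1.0
    linking_kernel: tuple[tuple[float, ...], ...] = field(
        default=DEFAULT_LINKING_KERNEL
    )

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        for name in ("alpha_theta", "v_theta", "alpha_l", "v_l", "theta_init"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        W = np.asarray(self.linking_kernel, dtype=np.float64)
        if W.shape != (3, 3):
            raise ValueError(f"linking_kernel must be 3x3, got {W.shape}")
        if W[1, 1] != 0:
            raise ValueError("linking_kernel centre must be 0")
        if (W < 0).any():
            raise ValueError("linking_kernel weights must be >= 0")

    @property
    def kernel(self) -> np.ndarray:
        return np.asarray(self.linking_kernel, dtype=np.float64)


def sts(layer: np.ndarray) -> np.ndarray:
    """Structure-tensor saliency: gradient magnitude rescaled to [0, 1] by
    its own maximum (identically 0 for a constant layer).  Signed residual
    layers are fine — only intensity differences matter."""
    g = gradient_magnitude(layer)
    m = g.max()
    return g / m if m > 0 else g


def normalize_feed(layer: np.ndarray) -> np.ndarray:
    """Affine map of a (possibly signed) layer onto [0, 1]; a constant
    layer maps to all zeros so it can never out-fire structure."""
    layer = np.asarray(layer, dtype=np.float64)
    lo, hi = layer.min(), layer.max()
    if hi <= lo:
        return np.zeros_like(layer)
    return (layer - lo) / (hi - lo)


def pcnn_firing_times(
    feed_a: np.ndarray,
    feed_b: np.ndarray,
    beta_a: np.ndarray,
    beta_b: np.ndarray,
    p: PcnnParams = PcnnParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Run the twin PCNNs and return their firing-time maps (T_a, T_b).

    Per modality, starting from Y = L = T = 0 and theta = theta_init, step
    n = 1..iterations updates::

        L(n)     = exp(-alpha_l) L(n-1) + v_l (W * Y(n-1))      # * = 2-D correlation, zero outside
        U(n)     = F (1 + beta L(n))
        Y(n)     = [U(n) >= theta(n-1)]
        T        = n where Y(n) = 1, else unchanged
        theta(n) = exp(-alpha_theta) theta(n-1) + v_theta Y(n)

    Neurons outside the grid never pulse (zero padding of Y).
    """
    shapes = {np.shape(x) for x in (feed_a, feed_b, beta_a, beta_b)}
    if len(shapes) != 1:
        raise DimensionError(f"feeds and saliency maps must share one shape, got {shapes}")
    W = p.kernel
    decay_l = np.exp(-p.alpha_l)
    decay_t = np.exp(-p.alpha_theta)
    out: list[np.ndarray] = []
    for F, beta in ((feed_a, beta_a), (feed_b, beta_b)):
        F = np.asarray(F, dtype=np.float64)
        beta = np.asarray(beta, dtype=np.float64)
        L = np.zeros_like(F)
        Y = np.zeros_like(F)
        theta = np.full_like(F, p.theta_init)
        T = np.zeros(F.shape, dtype=np.int64)
        for n in range(1, p.iterations + 1):
            L = decay_l * L + p.v_l * ndimage.correlate(Y, W, mode="constant", cval=0.0)
            U = F * (1.0 + beta * L)
            fired = U >= theta
            T[fired] = n
            theta = decay_t * theta + p.v_theta * fired
            Y = fired.astype(np.float64)
        out.append(T)
    return out[0], out[1]


def fuse_layer(
    layer_a: np.ndarray,
    layer_b: np.ndarray,
    p: PcnnParams = PcnnParams(),
    prefer_earlier: bool = False,
) -> np.ndarray:
    """Fuse one pair of detail layers by PCNN firing-time competition.

    ``layer_a`` occupies the structural (MRI) slot: it wins wherever
    T_a >= T_b.  ``prefer_earlier`` flips the comparison for users who read
    earlier (rather than more recent) firing as the stronger response.
    """
    layer_a = np.asarray(layer_a, dtype=np.float64)
    layer_b = np.asarray(layer_b, dtype=np.float64)
    if layer_a.shape != layer_b.shape:
        raise DimensionError(f"layer shapes differ: {layer_a.shape} vs {layer_b.shape}")
    t_a, t_b = pcnn_firing_times(
        normalize_feed(layer_a), normalize_feed(layer_b), sts(layer_a), sts(layer_b), p
    )
    take_a = (t_a <= t_b) if prefer_earlier else (t_a >= t_b)
    return np.where(take_a, layer_a, layer_b)
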