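"""Synthetic registered image-pair generator.

Real fusion inputs are a structural scan (MRI-like: sharp anatomical
boundaries, fine texture, no colour) and a functional scan (PET/SPECT-like:
smooth colour-coded activity blobs, little structure).  The phantoms here
emulate exactly those contrasts on a shared elliptical "anatomy" layout so
a registered pair can be generated from one spec:

- the structural phantom is grayscale (s = 0): nested elliptical regions
  with step edges of height ``edge_contrast``, sinusoidal fine texture of
  amplitude ``texture_amp`` inside the head, plus Gaussian noise;
- the functional phantom is colour: ``n_blobs`` Gaussian-profile activity
  blobs with distinct hues and full saturation inside the same head
  outline, smooth everywhere (no step edges).

Everything is deterministic given ``seed``.  The phantoms are parametric
rather than stored fixtures so tests can sweep contrast and noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import gaussian_blur
from .image_io import HsvImage

__all__ = ["PhantomSpec", "make_structural", "make_functional", "make_pair"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one registered phantom pair."""

    size: tuple[int, int] = (128, 128)
    seed: int = 0
    n_blobs: int = 3
    texture_amp: float = 0.15
    edge_contrast: float = 0.5
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.size[0] < 32 or self.size[1] < 32:
            raise ValueError(f"size must be at least 32x32, got {self.size}")
        for name in ("texture_amp", "edge_contrast", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")


def _grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.size
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    return yy, xx


def _anatomy(spec: PhantomSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shared layout: the head outline and inner structure masks, drawn
    from the anatomy-dedicated random stream so structural and functional
    phantoms of one spec are registered by construction."""
    rng = np.random.default_rng([spec.seed, 0])
    yy, xx = _grids(spec)
    head = (xx / 0.88) ** 2 + (yy / 0.92) ** 2 <= 1.0
    inner: list[np.ndarray] = []
    for _ in range(3):
        cy, cx = rng.uniform(-0.45, 0.45, size=2)
        ry, rx = rng.uniform(0.12, 0.3, size=2)
        inner.append(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0)
    return head, inner


def make_structural(spec: PhantomSpec) -> HsvImage:
    """Edge-rich grayscale structural phantom (returned as HSV with s=0)."""
    rng = np.random.default_rng([spec.seed, 1])
    yy, xx = _grids(spec)
    head, inner = _anatomy(spec)
    v = np.full(spec.size, 0.05)
    base = 0.05 + spec.edge_contrast  # bright anatomy on dark ground
    v[head] = base
    for k, mask in enumerate(inner):
        # alternate hyper-/hypo-intense structures, like tissue classes
        step = spec.edge_contrast * (0.6 if k % 2 == 0 else -0.5)
        v[mask & head] = base + step
    if spec.texture_amp > 0:
        fy, fx = rng.uniform(6.0, 14.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        texture = np.sin(np.pi * fy * yy + phase[0]) * np.sin(np.pi * fx * xx + phase[1])
        v = v + spec.texture_amp * texture * head
    if spec.noise_sigma > 0:
        v = v + rng.normal(0.0, spec.noise_sigma, size=spec.size)
    return HsvImage.from_gray(np.clip(v, 0.0, 1.0))


def make_functional(spec: PhantomSpec) -> HsvImage:
    """Smooth colour functional phantom: Gaussian activity blobs with
    distinct hues inside the same head outline as the structural phantom."""
    rng = np.random.default_rng([spec.seed, 2])
    yy, xx = _grids(spec)
    head, inner = _anatomy(spec)
    profiles = np.zeros((max(spec.n_blobs, 1), *spec.size))
    for k in range(spec.n_blobs):
        region = inner[k % len(inner)] & head
        if region.any():
            idx = rng.integers(region.sum())
            cy, cx = yy[region][idx], xx[region][idx]
        else:  # degenerate layout; fall back to the head centre
            cy, cx = 0.0, 0.0
        width = rng.uniform(0.2, 0.35)
        amp = rng.uniform(0.35, 0.55)  # functional value stays dimmer than the structural anatomy
        profiles[k] = amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2)))
    # overlapping foci combine non-additively: each keeps its own amplitude
    v = profiles.max(axis=0) + gaussian_blur(0.1 * head.astype(float), 3.0)
    v = np.clip(v, 0.0, 1.0)
    if spec.n_blobs > 0:
        hues = (np.arange(spec.n_blobs) / spec.n_blobs + 0.05) % 1.0
        h = hues[profiles.argmax(axis=0)]
        in_blob = profiles.max(axis=0) > 0.05
        h = np.where(in_blob, h, 0.0)
        s = np.where(in_blob, 1.0, 0.0)
    else:
        v = np.zeros(spec.size)
        h = np.zeros(spec.size)
        s = np.zeros(spec.size)
    return HsvImage(h=h, s=s, v=v)


def make_pair(spec: PhantomSpec) -> tuple[HsvImage, HsvImage]:
    """Registered (structural, functional) pair sharing one anatomy layout,
    with blob centres placed inside the anatomy regions."""
    return make_structural(spec), make_functional(spec)
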