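"""Objective fusion-quality metrics.

Seven indicators, each computed on a triple (a, b, f) of aligned gray
images — the two source value channels and the fused value channel:

- ``entropy``: Shannon entropy (bits) of the fused image's 8-bit histogram;
  more texture, more bits.
- ``mssim``: mean of SSIM(a, f) and SSIM(b, f), the standard 11x11
  Gaussian-windowed structural similarity.
- ``scd``: sum of correlations of differences, r(a, f-b) + r(b, f-a); each
  difference image should recover the other source, so 2 is ideal.
- ``qabf``: Xydeas-Petrovic gradient-based edge-transfer index — how much
  of each source's Sobel edge strength and orientation survives in f,
  sigmoid-mapped and weighted by source edge strength.
- ``piella``: Piella-Heijmans Q_S — the universal image-quality index Q0
  between each source and f in sliding 8x8 windows, weighted by local
  saliency (variance).
- ``qy``: Yang's index — per 7x7 window, a saliency-weighted SSIM blend
  where the sources agree (local SSIM(a,b) >= 0.75) and the better of the
  two SSIMs where they conflict.
- ``fmi``: feature mutual information — normalized mutual information
  between gradient-magnitude feature maps of each source and f.

All metrics operate on value channels and are symmetric in (a, b).
Windowed metrics share one degenerate-window convention: zero total
saliency gives weight 1/2, and zero-variance similarity factors count as
perfect agreement (or are stabilized by the SSIM constants).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .exceptions import DimensionError
from .filters import gradient_magnitude

__all__ = [
    "MetricsReport",
    "entropy",
    "mssim",
    "scd",
    "qabf",
    "piella",
    "qy",
    "fmi",
    "evaluate",
]

# Xydeas-Petrovic sigmoid constants (edge-strength and orientation branches).
QABF_GAMMA_G, QABF_KAPPA_G, QABF_SIGMA_G = 0.9994, -15.0, 0.5
QABF_GAMMA_A, QABF_KAPPA_A, QABF_SIGMA_A = 0.9879, -22.0, 0.8

_SSIM_KW = dict(
    win_size=11,
    gaussian_weights=True,
    sigma=1.5,
    use_sample_covariance=False,
    K1=0.01,
    K2=0.03,
    data_range=1.0,
)


def _check_triple(*imgs: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(x, dtype=np.float64) for x in imgs]
    shapes = {x.shape for x in out}
    if len(shapes) != 1:
        raise DimensionError(f"images must share one shape, got {shapes}")
    return out


def entropy(f: np.ndarray) -> float:
    """Shannon entropy (base 2) of the 256-bin histogram of the 8-bit
    quantized image; empty bins contribute nothing."""
    q = np.clip(np.round(np.asarray(f, dtype=np.float64) * 255.0), 0, 255).astype(int)
    p = np.bincount(q.ravel(), minlength=256).astype(np.float64)
    p /= p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)


def mssim(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Mean of SSIM(a, f) and SSIM(b, f) with the standard 11x11 Gaussian
    window (sigma 1.5), K1=0.01, K2=0.03, unit dynamic range."""
    a, b, f = _check_triple(a, b, f)
    s_af = structural_similarity(a, f, **_SSIM_KW)
    s_bf = structural_similarity(b, f, **_SSIM_KW)
    return float((s_af + s_bf) / 2.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over all pixels; 0 by convention if either side
    is constant."""
    x = x.ravel() - x.mean()
    y = y.ravel() - y.mean()
    denom = math.sqrt(float(x @ x)) * math.sqrt(float(y @ y))
    if denom == 0:
        return 0.0
    return float(x @ y) / denom


def scd(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Sum of correlations of differences: r(a, f-b) + r(b, f-a)."""
    a, b, f = _check_triple(a, b, f)
    return _pearson(a, f - b) + _pearson(b, f - a)


def _sobel_edges(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel edge strength and orientation.

    Orientation is arctan(sy/sx) in (-pi/2, pi/2], folded to +pi/2 when the
    horizontal response vanishes (orientation is defined modulo pi).
    """
    sx = ndimage.sobel(img, axis=1, mode="reflect")
    sy = ndimage.sobel(img, axis=0, mode="reflect")
    g = np.hypot(sx, sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.arctan(sy / sx)
    alpha = np.where(sx == 0, np.pi / 2, alpha)
    return g, alpha


def _edge_preservation(g_s, a_s, g_f, a_f) -> np.ndarray:
    """Q^{sF}: sigmoid-mapped agreement of edge strength and orientation
    between one source and the fused image."""
    num = np.minimum(g_s, g_f)
    den = np.maximum(g_s, g_f)
    with np.errstate(invalid="ignore"):
        G = np.where(den > 0, num / den, 1.0)
    A = 1.0 - np.abs(a_s - a_f) / (np.pi / 2)
    Qg = QABF_GAMMA_G / (1.0 + np.exp(QABF_KAPPA_G * (G - QABF_SIGMA_G)))
    Qa = QABF_GAMMA_A / (1.0 + np.exp(QABF_KAPPA_A * (A - QABF_SIGMA_A)))
    return Qg * Qa


def qabf(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Xydeas-Petrovic gradient-based edge-transfer index (weights L=1)."""
    a, b, f = _check_triple(a, b, f)
    g_a, al_a = _sobel_edges(a)
    g_b, al_b = _sobel_edges(b)
    g_f, al_f = _sobel_edges(f)
    q_af = _edge_preservation(g_a, al_a, g_f, al_f)
    q_bf = _edge_preservation(g_b, al_b, g_f, al_f)
    wsum = (g_a + g_b).sum()
    if wsum == 0:
        return 0.0
    return float((q_af * g_a + q_bf * g_b).sum() / wsum)


def _window_moments(x: np.ndarray, w: int) -> np.ndarray:
    """Mean of x over every fully interior w x w sliding window."""
    m = ndimage.uniform_filter(x, size=w, mode="constant")
    lo = w // 2
    return m[lo : x.shape[0] - (w - 1 - lo), lo : x.shape[1] - (w - 1 - lo)]


def _local_stats(a, b, f, w):
    ma, mb, mf = (_window_moments(x, w) for x in (a, b, f))
    sa = _window_moments(a * a, w) - ma * ma
    sb = _window_moments(b * b, w) - mb * mb
    sf = _window_moments(f * f, w) - mf * mf
    caf = _window_moments(a * f, w) - ma * mf
    cbf = _window_moments(b * f, w) - mb * mf
    return ma, mb, mf, sa, sb, sf, caf, cbf


def _q0(mx, mf, sx, sf, cxf) -> np.ndarray:
    """Universal image-quality index per window; degenerate factors count
    as perfect agreement."""
    lum_den = mx * mx + mf * mf
    cs_den = sx + sf
    with np.errstate(invalid="ignore", divide="ignore"):
        lum = np.where(lum_den > 0, 2.0 * mx * mf / lum_den, 1.0)
        cs = np.where(cs_den > 0, 2.0 * cxf / cs_den, 1.0)
    return lum * cs


def piella(a: np.ndarray, b: np.ndarray, f: np.ndarray, window: int = 8) -> float:
    """Piella-Heijmans Q_S: saliency-weighted Q0 over sliding windows,
    saliency = local variance, weight 1/2 when both windows are flat."""
    a, b, f = _check_triple(a, b, f)
    if min(a.shape) < window:
        raise DimensionError(f"image smaller than the {window}x{window} window")
    ma, mb, mf, sa, sb, sf, caf, cbf = _local_stats(a, b, f, window)
    ssum = sa + sb
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(ssum > 0, sa / ssum, 0.5)
    q = lam * _q0(ma, mf, sa, sf, caf) + (1.0 - lam) * _q0(mb, mf, sb, sf, cbf)
    return float(q.mean())


def _local_ssim(mx, my, sx, sy, cxy, k1=0.01, k2=0.03) -> np.ndarray:
    c1, c2 = k1 * k1, k2 * k2
    return ((2 * mx * my + c1) * (2 * cxy + c2)) / (
        (mx * mx + my * my + c1) * (sx + sy + c2)
    )


def qy(a: np.ndarray, b: np.ndarray, f: np.ndarray, window: int = 7) -> float:
    """Yang's structure index: where the sources agree locally
    (SSIM(a,b) >= 0.75) a saliency-weighted SSIM blend, elsewhere the
    better of SSIM(a,f) and SSIM(b,f); averaged over sliding windows."""
    a, b, f = _check_triple(a, b, f)
    if min(a.shape) < window:
        raise DimensionError(f"image smaller than the {window}x{window} window")
    ma, mb, mf, sa, sb, sf, caf, cbf = _local_stats(a, b, f, window)
    cab = _window_moments(a * b, window) - ma * mb
    s_ab = _local_ssim(ma, mb, sa, sb, cab)
    s_af = _local_ssim(ma, mf, sa, sf, caf)
    s_bf = _local_ssim(mb, mf, sb, sf, cbf)
    ssum = sa + sb
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(ssum > 0, sa / ssum, 0.5)
    blended = lam * s_af + (1.0 - lam) * s_bf
    q = np.where(s_ab >= 0.75, blended, np.maximum(s_af, s_bf))
    return float(q.mean())


def _hist_mi(x: np.ndarray, y: np.ndarray, bins: int = 256) -> float:
    """Normalized mutual information 2 I(x;y) / (H(x) + H(y)) from a joint
    histogram with per-variable min-max binning."""

    def digitize(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi <= lo:
            return np.zeros(v.shape, dtype=np.int64)
        idx = np.floor((v - lo) / (hi - lo) * bins).astype(np.int64)
        return np.minimum(idx, bins - 1)

    ix, iy = digitize(x), digitize(y)
    joint = np.bincount(ix.ravel() * bins + iy.ravel(), minlength=bins * bins)
    p = joint.astype(np.float64).reshape(bins, bins) / ix.size
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def h(q: np.ndarray) -> float:
        nz = q[q > 0]
        return float(-(nz * np.log2(nz)).sum())

    hx, hy, hxy = h(px), h(py), h(p)
    if hx + hy == 0:
        return 0.0
    return 2.0 * (hx + hy - hxy) / (hx + hy)


def fmi(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Gradient-feature mutual information: mean of the normalized MIs
    between the gradient-magnitude maps of each source and of f."""
    a, b, f = _check_triple(a, b, f)
    feat_a, feat_b, feat_f = (gradient_magnitude(x) for x in (a, b, f))
    return (_hist_mi(feat_a, feat_f) + _hist_mi(feat_b, feat_f)) / 2.0


@dataclass
class MetricsReport:
    """The seven scalar quality scores for one (a, b, f) triple."""

    entropy: float
    piella: float
    fmi: float
    qy: float
    qabf: float
    scd: float
    mssim: float

    FIELDS = ("entropy", "piella", "fmi", "qy", "qabf", "scd", "mssim")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(self.FIELDS)
            writer.writerow(f"{getattr(self, k):.6f}" for k in self.FIELDS)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetricsReport":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(**{k: float(rows[0][k]) for k in cls.FIELDS})


def evaluate(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> MetricsReport:
    """All seven metrics for one fusion triple, in one report."""
    a, b, f = _check_triple(a, b, f)
    return MetricsReport(
        entropy=entropy(f),
        piella=piella(a, b, f),
        fmi=fmi(a, b, f),
        qy=qy(a, b, f),
        qabf=qabf(a, b, f),
        scd=scd(a, b, f),
        mssim=mssim(a, b, f),
    )
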