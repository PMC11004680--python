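"""Independent reference implementations used only by the tests.

Every function here recomputes a quantity with naive scalar loops (or
closed formulas) straight from the published definitions, deliberately
sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np

# --------------------------------------------------------------------------
# colour


def rgb_to_hsv_scalar(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Hexcone RGB->HSV for one pixel, h in [0, 1)."""
    mx, mn = max(r, g, b), min(r, g, b)
    c = mx - mn
    if c == 0:
        h = 0.0
    elif mx == r:
        h = ((g - b) / c) % 6
    elif mx == g:
        h = (b - r) / c + 2
    else:
        h = (r - g) / c + 4
    h /= 6.0
    s = 0.0 if mx == 0 else c / mx
    return h, s, mx


# --------------------------------------------------------------------------
# filters


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Truncated-at-4-sigma unit-sum Gaussian, radius int(4*sigma + 0.5)."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_dense(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct dense 2-D convolution with the truncated kernel, symmetric
    padding."""
    k1 = gaussian_kernel_1d(sigma)
    k2 = np.outer(k1, k1)
    r = len(k1) // 2
    pad = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (pad[i : i + 2 * r + 1, j : j + 2 * r + 1] * k2).sum()
    return out


def gradient_magnitude_loop(img: np.ndarray) -> np.ndarray:
    """Per-pixel central differences (one-sided at borders)."""
    h, w = img.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            if 0 < i < h - 1:
                gy = (img[i + 1, j] - img[i - 1, j]) / 2.0
            elif i == 0:
                gy = img[1, j] - img[0, j]
            else:
                gy = img[h - 1, j] - img[h - 2, j]
            if 0 < j < w - 1:
                gx = (img[i, j + 1] - img[i, j - 1]) / 2.0
            elif j == 0:
                gx = img[i, 1] - img[i, 0]
            else:
                gx = img[i, w - 1] - img[i, w - 2]
            out[i, j] = math.hypot(gx, gy)
    return out


def guided_filter_loop(
    x: np.ndarray, I: np.ndarray, radius: int, eps: float
) -> np.ndarray:
    """Windowed linear regression per pixel, then window-averaged a, b."""
    h, w = x.shape
    xp = np.pad(x, radius, mode="symmetric")
    Ip = np.pad(I, radius, mode="symmetric")
    a = np.empty((h, w))
    b = np.empty((h, w))
    size = 2 * radius + 1
    for i in range(h):
        for j in range(w):
            Iw = Ip[i : i + size, j : j + size]
            xw = xp[i : i + size, j : j + size]
            m_I = Iw.mean()
            m_p = xw.mean()
            var = (Iw * Iw).mean() - m_I * m_I
            cov = (Iw * xw).mean() - m_I * m_p
            a[i, j] = cov / (var + eps)
            b[i, j] = m_p - a[i, j] * m_I
    ap = np.pad(a, radius, mode="symmetric")
    bp = np.pad(b, radius, mode="symmetric")
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (
                ap[i : i + size, j : j + size].mean() * I[i, j]
                + bp[i : i + size, j : j + size].mean()
            )
    return out


def box_mean_loop(x: np.ndarray, radius: int) -> np.ndarray:
    h, w = x.shape
    xp = np.pad(x, radius, mode="symmetric")
    size = 2 * radius + 1
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = xp[i : i + size, j : j + size].mean()
    return out


# --------------------------------------------------------------------------
# PCNN


def pcnn_times_loop(F, beta, kernel, iterations, alpha_l, v_l, alpha_theta, v_theta, theta_init):
    """One simplified PCNN simulated pixel by pixel, iteration by
    iteration, with pure Python loops; returns the firing-time map."""
    h, w = F.shape
    K = [list(map(float, row)) for row in kernel]
    L = [[0.0] * w for _ in range(h)]
    Y = [[0.0] * w for _ in range(h)]
    theta = [[float(theta_init)] * w for _ in range(h)]
    T = [[0] * w for _ in range(h)]
    dl = math.exp(-alpha_l)
    dt = math.exp(-alpha_theta)
    for n in range(1, iterations + 1):
        newL = [[0.0] * w for _ in range(h)]
        for i in range(h):
            for j in range(w):
                link = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w:
                            link += K[di + 1][dj + 1] * Y[ii][jj]
                newL[i][j] = dl * L[i][j] + v_l * link
        L = newL
        newY = [[0.0] * w for _ in range(h)]
        for i in range(h):
            for j in range(w):
                U = F[i, j] * (1.0 + beta[i, j] * L[i][j])
                if U >= theta[i][j]:
                    newY[i][j] = 1.0
                    T[i][j] = n
                theta[i][j] = dt * theta[i][j] + v_theta * newY[i][j]
        Y = newY
    return np.array(T, dtype=np.int64)


# --------------------------------------------------------------------------
# metrics


def ssim_windowed_loop(x: np.ndarray, y: np.ndarray) -> float:
    """11x11 Gaussian-window SSIM (sigma 1.5, K1=0.01, K2=0.03, range 1),
    averaged over fully interior windows."""
    r = 5
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / 1.5) ** 2)
    g /= g.sum()
    w2 = np.outer(g, g)
    c1, c2 = 0.01**2, 0.03**2
    h, w = x.shape
    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            xw = x[i - r : i + r + 1, j - r : j + r + 1]
            yw = y[i - r : i + r + 1, j - r : j + r + 1]
            ux = (w2 * xw).sum()
            uy = (w2 * yw).sum()
            vx = (w2 * xw * xw).sum() - ux * ux
            vy = (w2 * yw * yw).sum() - uy * uy
            vxy = (w2 * xw * yw).sum() - ux * uy
            vals.append(
                ((2 * ux * uy + c1) * (2 * vxy + c2))
                / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def pearson_loop(x: np.ndarray, y: np.ndarray) -> float:
    xs = x.ravel().tolist()
    ys = y.ravel().tolist()
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((v - mx) ** 2 for v in xs)
    syy = sum((v - my) ** 2 for v in ys)
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    d = math.sqrt(sxx) * math.sqrt(syy)
    return 0.0 if d == 0 else sxy / d


def scd_loop(a, b, f) -> float:
    return pearson_loop(a, f - b) + pearson_loop(b, f - a)


_KX = ((-1, 0, 1), (-2, 0, 2), (-1, 0, 1))
_KY = ((-1, -2, -1), (0, 0, 0), (1, 2, 1))


def sobel_loop(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel strength/orientation by per-pixel 3x3 correlation, symmetric
    padding; orientation folded to pi/2 where the horizontal response is 0."""
    pad = np.pad(img, 1, mode="symmetric")
    h, w = img.shape
    g = np.empty((h, w))
    alpha = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            sx = sy = 0.0
            for u in range(3):
                for v in range(3):
                    sx += _KX[u][v] * pad[i + u, j + v]
                    sy += _KY[u][v] * pad[i + u, j + v]
            g[i, j] = math.hypot(sx, sy)
            alpha[i, j] = math.pi / 2 if sx == 0 else math.atan(sy / sx)
    return g, alpha


def qabf_loop(a, b, f) -> float:
    """Literal transcription of the Xydeas-Petrovic index."""
    gg, kg, sg = 0.9994, -15.0, 0.5
    ga_, ka, sa_ = 0.9879, -22.0, 0.8
    g_a, al_a = sobel_loop(a)
    g_b, al_b = sobel_loop(b)
    g_f, al_f = sobel_loop(f)
    num = den = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for gs, als, w in ((g_a, al_a, g_a), (g_b, al_b, g_b)):
                hi = max(gs[i, j], g_f[i, j])
                G = 1.0 if hi == 0 else min(gs[i, j], g_f[i, j]) / hi
                A = 1.0 - abs(als[i, j] - al_f[i, j]) / (math.pi / 2)
                qg = gg / (1.0 + math.exp(kg * (G - sg)))
                qa = ga_ / (1.0 + math.exp(ka * (A - sa_)))
                num += qg * qa * w[i, j]
                den += w[i, j]
    return 0.0 if den == 0 else num / den


def _window_stats(xw, yw):
    mx = xw.mean()
    my = yw.mean()
    sx = (xw * xw).mean() - mx * mx
    sy = (yw * yw).mean() - my * my
    cxy = (xw * yw).mean() - mx * my
    return mx, my, sx, sy, cxy


def piella_loop(a, b, f, window: int = 8) -> float:
    vals = []
    for i in range(a.shape[0] - window + 1):
        for j in range(a.shape[1] - window + 1):
            aw = a[i : i + window, j : j + window]
            bw = b[i : i + window, j : j + window]
            fw = f[i : i + window, j : j + window]

            def q0(xw):
                mx, mf_, sx, sf_, cxf = _window_stats(xw, fw)
                lum_den = mx * mx + mf_ * mf_
                lum = 1.0 if lum_den == 0 else 2 * mx * mf_ / lum_den
                cs_den = sx + sf_
                cs = 1.0 if cs_den == 0 else 2 * cxf / cs_den
                return lum * cs

            sa = (aw * aw).mean() - aw.mean() ** 2
            sb = (bw * bw).mean() - bw.mean() ** 2
            lam = 0.5 if sa + sb == 0 else sa / (sa + sb)
            vals.append(lam * q0(aw) + (1 - lam) * q0(bw))
    return float(np.mean(vals))


def qy_loop(a, b, f, window: int = 7) -> float:
    c1, c2 = 0.01**2, 0.03**2

    def ssim_w(xw, yw):
        mx, my, sx, sy, cxy = _window_stats(xw, yw)
        return ((2 * mx * my + c1) * (2 * cxy + c2)) / (
            (mx * mx + my * my + c1) * (sx + sy + c2)
        )

    vals = []
    for i in range(a.shape[0] - window + 1):
        for j in range(a.shape[1] - window + 1):
            aw = a[i : i + window, j : j + window]
            bw = b[i : i + window, j : j + window]
            fw = f[i : i + window, j : j + window]
            s_ab = ssim_w(aw, bw)
            s_af = ssim_w(aw, fw)
            s_bf = ssim_w(bw, fw)
            if s_ab >= 0.75:
                sa = (aw * aw).mean() - aw.mean() ** 2
                sb = (bw * bw).mean() - bw.mean() ** 2
                lam = 0.5 if sa + sb == 0 else sa / (sa + sb)
                vals.append(lam * s_af + (1 - lam) * s_bf)
            else:
                vals.append(max(s_af, s_bf))
    return float(np.mean(vals))


def _entropy_bits(p: np.ndarray) -> float:
    return float(sum(-v * math.log2(v) for v in p.ravel() if v > 0))


def fmi_loop(a, b, f, bins: int = 256) -> float:
    """Gradient-feature normalized MI recomputed with explicit joint
    histogram accumulation."""

    def digitize(v):
        lo, hi = v.min(), v.max()
        if hi <= lo:
            return np.zeros(v.shape, dtype=int)
        idx = np.floor((v - lo) / (hi - lo) * bins).astype(int)
        idx[idx == bins] = bins - 1
        return idx

    def nmi(x, y):
        ix, iy = digitize(x), digitize(y)
        joint = np.zeros((bins, bins))
        for u, v in zip(ix.ravel(), iy.ravel()):
            joint[u, v] += 1
        joint /= joint.sum()
        hx = _entropy_bits(joint.sum(axis=1))
        hy = _entropy_bits(joint.sum(axis=0))
        hxy = _entropy_bits(joint)
        return 0.0 if hx + hy == 0 else 2.0 * (hx + hy - hxy) / (hx + hy)

    fa, fb, ff = (gradient_magnitude_loop(x) for x in (a, b, f))
    return (nmi(fa, ff) + nmi(fb, ff)) / 2.0
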