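"""Optional contrast adjustment of source value channels.

Low inter-tissue contrast in raw modality images can mask detail the
decomposition would otherwise separate.  A percentile linear stretch is the
simplest monotone remedy: it never reorders pixels and is the identity on an
image that already spans [0, 1] with (0, 100) percentiles.  It is OFF by
default so the default pipeline runs exactly the printed fusion equations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["enhance_contrast"]


def enhance_contrast(
    img: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Linear stretch mapping the ``low_pct`` percentile to 0 and the
    ``high_pct`` percentile to 1, clipped to [0, 1].

    A degenerate range (constant image, or equal percentiles) returns the
    input unchanged rather than dividing by zero.
    """
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    img = np.asarray(img, dtype=np.float64)
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi <= lo:
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)
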