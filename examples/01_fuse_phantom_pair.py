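"""Fuse a synthetic structural/functional phantom pair end to end.

Generates a registered pair (edge-rich grayscale "MRI", smooth colour
"SPECT"), fuses them, and scores the result with the seven quality metrics.
"""

import numpy as np

from medfuse import FusionConfig, PhantomSpec, evaluate, fuse_pair, make_pair

structural, functional = make_pair(PhantomSpec(size=(128, 128), seed=7))
fused = fuse_pair(structural, functional, FusionConfig())

print(f"structural value std : {structural.v.std():.4f}")
print(f"functional value std : {functional.v.std():.4f}")
print(f"fused value std      : {fused.v.std():.4f}")
print(f"hue deviation        : {np.abs(fused.h - functional.h).max():.4f}")
print()
report = evaluate(structural.v, functional.v, fused.v)
for name, value in report.to_dict().items():
    print(f"{name:8s} = {value:.4f}")

# The fused std exceeds the functional std (structural contrast was added)
# while the hue deviation is exactly 0 (colour passes through untouched).
# Of the metrics, entropy is in bits (texture richness of the fused image);
# piella/qy/qabf/mssim approach 1 and scd approaches 2 for ideal fusion.
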