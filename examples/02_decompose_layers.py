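"""Decompose one image into its seven MLGEPF sublayers.

Shows where the energy of an edge-rich image lands — small-scale texture in
SC, edges in LC, smooth base in BC — and that the layers sum back to the
input exactly.
"""

import numpy as np

from medfuse import PhantomSpec, make_structural, mlgepf_decompose, recompose

img = make_structural(PhantomSpec(size=(128, 128), seed=3)).v
stack = mlgepf_decompose(img)

total = sum(np.abs(l).sum() for l in (*stack.sc, *stack.lc, stack.bc))
for i, (sc, lc) in enumerate(zip(stack.sc, stack.lc), start=1):
    print(
        f"level {i}: SC share = {np.abs(sc).sum() / total:.3f}, "
        f"LC share = {np.abs(lc).sum() / total:.3f}"
    )
print(f"BC share = {np.abs(stack.bc).sum() / total:.3f}")
print(f"reconstruction error = {np.abs(recompose(stack) - img).max():.2e}")

# SC/LC shares shrink with level (each level sees an already-smoothed base);
# the reconstruction error is at float rounding, ~1e-16: the decomposition
# is exactly additive by construction.
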