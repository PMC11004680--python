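# Methods

## Model overview

The package fuses a co-registered structural/functional image pair in HSV
space. Fusion operates on value channels only; the functional image's hue
and saturation pass through to the output unchanged (a config switch also
routes saturation through the fusion machinery). Registration is a
precondition: shape mismatches are hard errors, never resampled away.
Internally every image is float64 in [0, 1]; files are converted once at
read time and quantized once at write time, so no 8-bit rounding
accumulates through the filter cascade. The hexcone HSV convention with
h ∈ [0, 1) is used throughout.

## Decomposition

Each value channel passes through a three-level cascade. At every level
the current base image is filtered twice: by a guided filter whose
guidance is the base minus its own gradient magnitude, and by a Gaussian.
The guided residual is the small-scale component SC(i), the gap between
guided and Gaussian outputs is the large-scale component LC(i), and the
Gaussian output becomes the next base; the final base is the background
BC. Three properties fix this arrangement:

- SC is the texture the edge-preserving filter removes, so it carries fine
  detail;
- LC is content the guided filter keeps but the Gaussian destroys, i.e.
  edges;
- the split telescopes (base = SC + LC + next base), so the seven layers
  sum back to the input exactly, for *any* filter parameters. Layers are
  therefore stored signed and never clipped; the single clip to [0, 1]
  happens after the fused layers are summed.

The guidance image is recomputed from each level's own input ("fresh
guidance per iteration"), one guided-filter pass per level. The Gaussian
chain — rather than the guided chain — feeds the next level, so BC equals
the composition of the three Gaussian blurs; this is asserted in the
tests. Whether the guidance should be normalized is genuinely open; it is
used as-is (signed, unclipped), since the guided filter's local linear
model needs no range restriction.

### Filter details

- **Gaussian**: separable, kernel truncated at 4σ and renormalized to unit
  sum; σ doubles per level (2, 4, 8 px by default) so level 1 captures
  texture and level 3 coarse structure.
- **Guided filter**: canonical box-window linear model. Per window,
  a = cov(I, p)/(var(I) + ε), b = mean(p) − a·mean(I); the output averages
  a and b over all windows covering a pixel: q = mean(a)·I + mean(b).
  Defaults radius 4, ε = 0.01 on the [0, 1] scale, identical across
  levels. Implemented with exact box sums (`uniform_filter`), so it
  matches the explicit windowed-regression loop to float rounding. Note
  the ε → ∞ and constant-guidance limits are the box mean applied
  *twice* (a → 0, b → window mean, and b is averaged again) — a property
  the tests pin down.
- **Gradient magnitude**: central differences in the interior, one-sided
  at borders (`np.gradient` semantics); invariant to constant offsets.
- **Borders**: reflect (symmetric) padding everywhere, avoiding dark
  halos that would contaminate BC.

## ST–PCNN fusion

Detail layers are fused by firing-time competition between twin simplified
pulse-coupled neural networks. Per modality and iteration n:

```
L(n) = exp(−α_L)·L(n−1) + V_L·(W ⊛ Y(n−1))
U(n) = F·(1 + β·L(n))
Y(n) = [U(n) ≥ θ(n−1)]
θ(n) = exp(−α_θ)·θ(n−1) + V_θ·Y(n)
```

with cold start Y = L = T = 0, θ = θ₀, and T recording the iteration of
the most recent pulse. β is the layer's gradient magnitude rescaled by its
own maximum (the structure-tensor saliency), so edge pixels couple more
strongly to neighbour pulses. The fused layer takes, per pixel, the source
whose T is larger — the more recently pulsing neuron — with ties going to
the structural slot. A config switch (`prefer_earlier_firing`) flips the
comparison for users who read earlier first-firing as the stronger
response; with the default long horizon, stronger stimuli refire more
often and hence more recently, so the two readings usually agree.

Defaults: 110 iterations, α_L = 1, V_L = 1, α_θ = 0.2, V_θ = 20, θ₀ = 1,
W the 8-neighbour kernel with weight 1 on edge neighbours and 0.5 on
diagonals. These are the canonical simplified-PCNN settings of the fusion
literature; V_θ ≫ 1 gives each neuron a long refractory period so firing
times separate stimulus strengths cleanly. Neurons outside the grid never
pulse (zero padding of Y).

Feeds are affinely normalized per layer to [0, 1] (constant layers map to
0, so a flat layer can never out-fire structure). This puts signed
residual layers of both modalities on a common scale, as the feeding
equation requires — at the cost of erasing amplitude differences *between*
modalities: a low-amplitude detail layer competes on equal footing once
normalized. The effect is visible in the metric comparison example, where
winner-take-all mixing prices down similarity-style scores on smooth
phantoms. This is the intended selection semantics, not a defect.

The background components fuse by pixelwise maximum: the background is
the best carrier of overall luminance, and the maximum never discards the
brighter base.

## Enhancement (optional, off by default)

A percentile linear stretch (defaults 1–99) of the value channels before
decomposition. It is monotone, bounded, and the identity on images already
spanning [0, 1] at (0, 100); constant images pass through unchanged. Off
by default so the default pipeline is exactly the fusion equations;
enabled per config or `--enhance`.

## Quality metrics

All seven operate on value channels and are symmetric in the sources.

- **entropy**: base-2 Shannon entropy of the 256-bin histogram of the
  8-bit-quantized fused image.
- **mssim**: mean of SSIM(a, f) and SSIM(b, f); 11×11 Gaussian window
  σ = 1.5, K₁ = 0.01, K₂ = 0.03, dynamic range 1.
- **scd**: r(a, f−b) + r(b, f−a) with global Pearson r; a constant
  difference image contributes 0 by convention.
- **qabf**: Sobel strength g and orientation α per image; per source,
  agreement ratios G = min/max (1 when both strengths are 0) and
  A = 1 − |Δα|/(π/2) pass through sigmoids with the standard constants
  (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879, κ_α = −22,
  σ_α = 0.8); products are averaged with weights g (L = 1). With these
  constants the orientation sigmoid at perfect agreement evaluates to
  0.9879/(1 + e^{−4.4}) ≈ 0.976, so the index's ceiling — attained at
  a = b = f — is ≈ 0.9748, not 1.
- **piella**: sliding 8×8 windows; per window the universal image-quality
  index Q0 between each source and f, weighted by λ = s_A/(s_A + s_B)
  with s the window variance (λ = 1/2 when both vanish; degenerate Q0
  factors count as perfect agreement).
- **qy**: sliding 7×7 windows; where local SSIM(a, b) ≥ 0.75 a λ-blend of
  SSIM(a, f) and SSIM(b, f), elsewhere their maximum.
- **fmi**: gradient-magnitude feature maps; mutual information from a
  global 256-bin joint histogram (per-variable min–max binning), each MI
  normalized by the mean of the two marginal entropies, averaged over the
  two sources. The global-histogram estimator carries a finite-sample
  positive bias that is material below roughly 256×256 (measured ≈ 0.14
  for independent 128² fields, ≈ 0.04 at 256²); identity still scores
  exactly 1 at any size.

Window sizes and constants are exposed as function parameters; windowed
statistics use population (divide-by-N) moments, to which Q0 is invariant.

## Synthetic phantoms

`medfuse.phantoms` generates registered pairs from one seeded spec, with
separate deterministic substreams for anatomy, texture/noise and blobs.
The structural phantom is bright anatomy on dark ground: a head ellipse at
0.05 + edge_contrast with alternating hyper-/hypo-intense inner ellipses
(±0.6/−0.5 of edge_contrast), sinusoidal fine texture (amplitude 0.15) and
additive Gaussian noise (σ = 0.01). The functional phantom places 3
Gaussian activity foci (widths 0.2–0.35 of the half-frame, amplitudes
0.35–0.55, combined by pointwise maximum so overlaps do not stack to full
scale) inside the same anatomy, over a heavily blurred base — smooth
everywhere, dimmer than the structural anatomy, with distinct hues at full
saturation inside blobs. These defaults encode the modality contrast the
pipeline targets: the structural source owns edges and texture, the
functional source owns colour and smooth intensity.

What the phantoms do **not** emulate: realistic tissue statistics, partial
volume effects, modality-specific noise (Rician, Poisson), intensity
nonuniformity, or registration error. Passing tests therefore certify the
pipeline's algebraic and selection properties and its qualitative
behaviour on controlled structure — not clinical image quality.

## Numerical choices and degenerate inputs

- Exact box sums make the guided filter bit-comparable (≤ 1e-10) to the
  brute-force windowed regression; PCNN firing-time maps are bit-equal to
  a scalar per-pixel simulation because the linking convolution sums
  exactly representable dyadic weights.
- Constant images: decomposition sends everything to BC; saliency and
  normalized feeds are 0; metric conventions (λ = 1/2, degenerate factors
  = 1, r = 0) avoid 0/0 without skewing scores.
- PCNN ties (T_a = T_b, including the both-never-fired case) resolve to
  the structural slot, which makes self-fusion an exact fixed point.
- Determinism: the pipeline has no randomness; phantoms are reproducible
  from the seed.

## Problem sizes

The test suite exercises images from 2×2 (error paths) to 256×256; oracle
comparisons run at ≤ 32×32 where scalar loops are exact and fast. The
acceptance script measures the end-to-end pipeline at 256×256 (about 2 s
on one CPU) and the property certificates at the sizes above.

## Known limitations

- The PCNN constants and guided-filter parameters are literature-standard
  defaults, not fitted values; results on real data will depend on them
  (all are config-exposed).
- Per-layer feed normalization equalizes modal amplitudes by design (see
  above).
- The Q^{AB/F} ceiling of ≈ 0.9748 (sigmoid constants) means perfect
  fusion does not score 1 on that index.
- Colour handling assumes the functional image carries the chroma; fusing
  two colour images of comparable chroma content is out of scope.
- No registration, resampling, DICOM/NIfTI or 3-D volume support.
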