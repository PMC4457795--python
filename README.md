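# retivote

Retinal vessel segmentation from color fundus photographs, aimed at
recovering **small peripheral vessels** as well as the main vascular tree.
Small vessels carry most of the early-diagnostic signal in diabetic
retinopathy and related conditions, but they are faint, thin, and routinely
missed both by segmentation algorithms and by first-observer manual
annotations. `retivote` implements an unsupervised pipeline built around a
local *gray-voting* contrast operator and a Gaussian-mixture pixel
classifier, with a fragment-complementation step that explicitly re-attaches
broken small-vessel pieces.

## Method

Given the green channel I of an RGB fundus image (the channel with the best
vessel/background contrast), inverted so vessels are bright:

1. **Gabor enhancement.** An anisotropic complex Gabor wavelet
   ψ(x) = exp(j k₀·x) exp(−|Ax|²/2), A = diag(ε^(−1/2), 1), is correlated
   with I at scale a = 3 over orientations θ ∈ {0°, 10°, …, 170°} (dense
   transform by FFT). The per-pixel maximum modulus over θ is the main-vessel
   response I_Gabor.
2. **Gray-voting.** For each pixel, the m×m window (m = 11) votes: neighbors
   with value ≥ Center − k count toward Num₁, the rest toward Num₂, and
   P_vote = Num₁·L + Num₂·N with L = M_max/(m²−1), N = −M_min/(m²−1) derived
   from the window extrema. The transition scale k (3/255 in the main pass)
   trades small-vessel sensitivity against noise.
3. **Fusion.** I_gv = I_Gabor · (1 − I_vessel), multiplying the rescaled
   Gabor response with the complement of the rescaled voting image.
4. **GMM classification.** The in-FOV intensities of I_gv are fitted with a
   K = 4 Gaussian mixture p(x) = Σᵢ ωᵢ 𝒩(x; μᵢ, σᵢ²) (K-means init, EM).
   Pixels are assigned to components by maximum posterior; the brightest
   component with non-negligible weight is the vessel layer I_GMM.
5. **Complementation.** A second, more permissive voting pass (k = −5/255)
   on I_gv is binarized (exact Otsu) into I_com. Every I_GMM component of
   ≤ T_seed = 30 pixels is treated as a broken-vessel seed and adopts the
   I_com fragment beneath it when that fragment has ≤ T_fragment = 100
   pixels.
6. **Fragment elimination.** Components with pixel count F < 14000 and
   squareness rate S = 100·F/(1 + mx²) > 0.2 are discarded as non-vessel
   blobs (mx: the larger maximum coordinate of the component).

Evaluation is pixel-wise against gold-standard masks: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, plus
disagreement overlays (TP green, FP blue, FN red).

No annotated data is required to test any of this: the package ships a
**synthetic fundus phantom** generator (branching vessel trees with known
per-pixel width, bright optic disc, dark fovea, circular field of view) so
every stage runs against exact ground truth.

## Worked example

```python
from retivote import (PhantomSpec, generate_phantom, PipelineConfig,
                      run_pipeline, confusion, metrics, jaccard)

phantom = generate_phantom(PhantomSpec(rng_seed=0, noise_sd=0.0,
                                       vessel_contrast=0.35))
result = run_pipeline(phantom.rgb, PipelineConfig(seed=0), fov=phantom.fov)

m = metrics(confusion(result["I_FINAL"], phantom.truth, phantom.fov))
print(f"sensitivity  {m.sensitivity:.4f}")
print(f"specificity  {m.specificity:.4f}")
print(f"accuracy     {m.accuracy:.4f}")
print(f"jaccard      {jaccard(result['I_FINAL'], phantom.truth, phantom.fov):.4f}")
print(f"pixels added by complementation: {result['manifest']['pixels_added']}")
```

prints

```
sensitivity  0.9138
specificity  0.9255
accuracy     0.9243
jaccard      0.5487
pixels added by complementation: 134
```

On this zero-noise, high-contrast 584×565 phantom the final mask recovers
91% of vessel pixels at 93% specificity; the Jaccard overlap of ~0.55
reflects the method's deliberate over-segmentation around thin vessels
(sensitivity is favored over specificity by design). `result` also holds
every intermediate (`I_Gabor`, `I_vessel`, `I_gv`, `I_GMM`, `I_com`, …) for
inspection.

The same pipeline is available from the shell:

```sh
retivote phantom --out demo --seed 0 --size 584x565
retivote run demo/image.png --fov demo/fov.png --out demo/run --save-intermediates
retivote evaluate --pred demo/run/I_FINAL.png --gold demo/truth.png \
                  --fov demo/fov.png --out demo/eval
```

Conventions: rasters are row-major, 0-based `(row, col)`; intensities are
normalized to [0, 1] on read (divide by 255 or 65535); masks are written as
0/255 single-channel PNG.

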