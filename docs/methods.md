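# Methods

This note documents the model, the parameter choices, the synthetic data
the package is validated on, and the numerical decisions a maintainer
should know about. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and pipeline

A fundus photograph's green channel shows vessels as dark curvilinear
structures on a brighter, slowly varying background, with a bright optic
disc and a darker fovea. The pipeline inverts the green channel once at
preprocessing so that vessels are the *bright* structure every subsequent
operator responds to. This single polarity choice matters: the gray-voting
operator separates a bright ridge center (nearly all neighbors below
`Center − k`, driving the vote strongly negative) cleanly from background,
whereas a dark local minimum would collect the same vote as flat
background (every neighbor passes the comparison and the vote saturates at
the window maximum). The multiplicative fusion `I_gv = I_Gabor (1 −
I_vessel)` is only vessel-selective under this convention: vessel pixels
map near 0 in the min–max rescaled voting image, so `1 − I_vessel` is
largest exactly on vessels, and the Gabor factor gates it to oriented
structure.

Stages and the arrays they produce:

| stage | output | operator |
|---|---|---|
| preprocess | `I_green` | green channel, inverted, FOV-masked |
| enhancement | `I_Gabor` | max-modulus anisotropic Gabor over 18 orientations |
| enhancement | `I_vessel` | gray-voting, m = 11, k = 3/255, L/N from window max/min |
| fusion | `I_gv` | `I_Gabor · (1 − I_vessel)`, both factors in [0, 1] |
| classification | `I_GMM` | vessel layer of a K = 4 intensity GMM |
| complement | `I_c`, `I_com` | gray-voting with k = −5/255, N = −M_max; exact-Otsu binarization of `−I_c` |
| complementation | `I_C_GMM` | fragment adoption, T_seed = 30, T_fragment = 100 |
| elimination | `I_FINAL` | squareness-rate filter, F < 14000 ∧ S > 0.2 removed |

## Parameters

* **Gabor** — scale `a = 3` px, anisotropy `ε = 4`, modulation
  `k₀ = (0, 3)`, orientations 0–170° in 10° steps. ε and k₀ follow the
  standard supervised-Gabor parameterization for retinal images; both are
  config-exposed. The wavelet's normalizing constant is folded into the
  final rescaling of `I_Gabor` to [0, 1] — only relative magnitudes reach
  the fusion, so any global constant cancels. The kernel grid is odd-sided
  with half-width `⌈4.8·a·√ε⌉`, where 4.8 = √(2 ln 1e5) makes the Gaussian
  envelope fall below 1e−5 at the border.
* **Gray-voting** — window m = 11; transition scale k = 3 gray levels
  (main pass) and −5 (complement pass), divided by 255 because all
  internal math is on normalized [0, 1] intensities. The complement pass
  uses N = −M_max/(m²−1) (both vote weights from the window maximum) as
  published; this may be a transcription slip for M_min but is implemented
  as printed and selectable via `l_mode`.
* **GMM** — K = 4 components (background, faint structure, vessels,
  bright extremes), tolerance 1e−6 relative log-likelihood, ≤ 500
  iterations, variance floor 1e−6, K-means (k-means++, 10 restarts)
  initialization under the single global seed. Assignment uses weighted
  posteriors by default; `weighted_assign=False` reproduces the literal
  unweighted-density rule.
* **Vessel-layer rule** — `brightest_major`: the highest-mean component
  holding ≥ 2% of the mixture mass. On some inputs EM isolates a
  sub-percent extreme-value tail as the top component; a strict
  highest-mean rule then selects a few hundred pixels and discards the
  actual vessel layer. The 2% floor distinguishes a tissue class from a
  tail. `highest`, `second_highest` and `index:i` remain available; with
  an inverted green channel the disc is dark, so no bright disc layer
  exists to skip and second-highest is not the right default.
* **Post-processing** — T_seed = 30 px, T_fragment = 100 px, 8-connectivity
  throughout; elimination constants 14000 px and 0.2. `mx` in the
  squareness rate defaults to the component's larger maximum *coordinate*
  (`mx_mode="coordinate"`); the alternative bounding-box-extent reading
  (`"extent"`) makes every adopted small fragment score far above 0.2 and
  be deleted, nullifying the complementation step, so it is exposed but
  not the default. Note the coordinate form makes the score
  position-dependent: compact blobs survive anywhere except near the
  raster origin. The 14000-px cut assumes full-size (~600×600) frames —
  on smaller rasters the entire vessel network falls below it and the
  config must scale `size_cut` down accordingly.
* **FOV handling** — `restrict` (default) confines voting windows,
  normalization, Otsu and the GMM sample to the field of view,
  renormalizing vote weights by the actual neighbor count at the FOV rim;
  `full` processes the whole raster. Absent a mask, the FOV is estimated
  as luminance > 0.02 after a disk-5 morphological closing.

## Numerical choices

* Window/kernel borders use symmetric (reflect) padding; the FFT-based
  Gabor transform reflect-pads by the kernel half-width before the
  frequency-domain product, so it equals direct spatial correlation with
  reflected boundaries (verified to 1e−8 relative).
* Otsu binarization is exact: between-class variance is maximized over
  every split of the sorted in-FOV sample, with no histogram binning.
  (Histogram-based implementations can shift the threshold on continuous
  data; the exact search is unambiguous and deterministic.)
* EM runs in log-space with `logsumexp`; the variance update uses the
  freshly updated mean. Collapsing components are re-floored with a
  warning rather than restarted.
* Degenerate inputs: constant images binarize to all-false with a warning;
  metrics with a zero denominator are NaN with a warning; a vote window
  with no in-FOV neighbors outputs 0.
* Ties: cluster assignment takes the first argmax; component labels follow
  raster-scan discovery order; the complementation seed uses the
  component's first pixel in row-major order (any pixel of the seed lies
  in the same complement component in practice, so the choice is
  inconsequential).
* Determinism: the single pipeline seed drives the K-means initialization,
  the only stochastic stage; identical (image, config, seed) gives
  bit-identical outputs, which the suite asserts.

## The synthetic phantom

`PhantomSpec`/`generate_phantom` emulate the geometry and photometry the
method depends on: branching random-walk vessel trees rooted at the disc,
Gaussian-profile intensity dips whose FWHM tapers from `main_width = 5` px
to `min_width = 1` px toward the tips, a textured background
(σ-18-smoothed noise), bright disc, dark fovea, additive sensor noise and
a circular FOV on a DRIVE-sized 584×565 raster. Defaults put the in-FOV
vessel fraction at roughly 7–13%, bracketing the 10–15% of manual
segmentations of real fundus images. The generator records per-pixel true
width, so sensitivity on *small* vessels (width ≤ 2 px) is scored
separately; ground truth is the set of pixels where the dip exceeds half
its local amplitude.

What the phantom does **not** emulate: pathology (exudates, hemorrhages),
vessel reflexes, inter-image illumination drift, and — by default —
contrast loss toward thin vessels (`contrast_taper = 1`). That last
simplification matters for interpretation: on a zero-noise, high-contrast
phantom the GMM layer alone already captures ~95% of small-vessel pixels,
leaving the complementation step little to add (its gain is strictly
positive but small in the acceptance check). Setting `contrast_taper < 1`
makes peripheral vessels fainter and shifts work from the GMM to the
complementation, at much lower overall overlap. Passing tests on the
phantom therefore validate the operators and their composition, not
clinical-grade performance on real images.

## Known limitations

* The method deliberately over-segments around thin vessels (a ~1-px halo
  from the scale-3 Gabor response), capping Jaccard near 0.55 on the
  phantom even at 91% sensitivity / 93% specificity; pixel metrics also
  say nothing about topological correctness.
* The elimination rule's position dependence (coordinate-based `mx`) and
  its very large size cut are kept for fidelity to the published
  procedure, not because they are well-founded; both are configurable.
* The complement-pass vote with k < 0 marks vessels and near-vessel halos
  alike; on a well-connected vasculature most complement fragments exceed
  T_fragment and are never adopted, so the complementation chiefly helps
  where small vessels are genuinely fragmented.
* Runtime is dominated by the EM loop (~25 s for a full-size frame at
  tolerance 1e−6 on one core); raising `gmm_tol` trades a few decimals of
  the fit for several-fold speedups.
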