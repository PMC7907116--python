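# Methods

This note records the models the package implements, the parameters that
matter, what the synthetic phantoms do and do not emulate, and the places
where the design was genuinely open and a choice had to be made.

## Segmentation model

A B-scan is labeled by maximizing `P(g,l) = P(g|l) · P_s(l) · P_V(l)` over
label maps `l` (0 = non-retina, 1..12 = NFL..RPE).

**Intensity term `P(g|l)`.** One 1-D Gaussian mixture per label (default 2
components, ≤ 3), fitted by plain EM with quantile initialization,
relative tolerance 1e-6, 200-iteration cap, and a variance floor of
0.25 gray² to keep noiseless inputs non-degenerate. The EM implementation
is in-package so the per-iteration log-likelihood trajectory is available;
it is non-decreasing up to the variance floor. During segmentation the
model is refitted three times against topology-regularized labelings, and
samples are taken from a one-pixel vertical erosion of each label's
region: the boundary rows carry interpolation blur and registration error,
and for 3–4 px bands (ELM, MZ) unclean samples visibly corrupt the means.
Labels with no support inherit pooled parameters (warned).

**Shape term `P_s(l)`.** Pixel-wise label frequencies over the atlas
entries, weighted by normalized cross-correlation between the aligned scan
and each atlas image (optionally restricted to the K most similar
entries), smoothed with ε = 1e-3 before taking logs. The background label
is included in the prior.

**Smoothness term `P_V(l)`.** Potts potentials on the 8-neighbour system:
+γ for an equal neighbour pair, −γ otherwise, with γ = 2·f_eq − 1
estimated from the atlas equal-pair frequency (the simplest member of the
analytic `f_eq − f_ne` family), scaled by a user weight β (default 0.3).

**Procedure.** Retina outline by coarse-to-fine gradient tracking on a
Gaussian pyramid: at the coarsest level the upper boundary is the *first*
strong dark→bright vertical edge per column and the lower boundary the
*last* strong bright→dark edge (a global gradient argmax locks onto
stronger interior edges where the inner layers vanish at the fovea);
refinement searches ±4 px around the upsampled curve at each finer level.
Outline landmarks at equal column fractions drive a thin-plate-spline
warp onto the atlas grid (both directions estimated, so the transform is
invertible in the practical sense). After ICM refinement (fixed 2×2
four-colour update schedule — vectorizable, deterministic, conditioning on
current neighbours) the layer topology is enforced by extracting one
separating row per column per adjacent layer pair (minimum disagreement
via prefix sums), smoothing across columns (moving average, width 7), and
ordering the boundary stack monotonically. The 13 band-edge curves are
mapped back to the native grid through the TPS at sub-pixel precision and
rasterized; rasterizing warped labels instead costs ~1 px on the thin
bands and was measurably worse.

The ICM stage never lowers the joint log-score relative to the
initialization (tested). The subsequent topology projection is a hard
anatomical constraint *outside* the probabilistic objective: on noiseless
scans, where per-pixel log-likelihoods are extreme, it can lower the
unconstrained score while fixing anatomy. The package treats topology as
inviolable and the objective-monotonicity guarantee as a property of the
probabilistic refinement only.

On noiseless same-family phantoms the mean 12-layer Dice is ≈ 0.92–0.93;
with moderate noise it is higher (≈ 0.96) because the intensity mixtures
are better conditioned. The thin bands (ELM 3 px, MZ 4 px) dominate the
residual error, as a sub-pixel boundary shift costs a large fraction of
such a band.

## Markers

**Relative reflectivity.** `I_n = (I − RV)/(R12 − RV) × 1000` with RV the
mean intensity at least 3 rows above the detected upper boundary (margin
against edge blur) and R12 the mean RPE intensity. The transform is
exactly invariant to affine intensity changes of the raw scan; negative
values are permitted. The 1st-order marker averages `I_n` in 10 column
bins per side (temporal/nasal), excluding a central region of half-width
15% of the image width where the inner layers vanish.

**MGRF Gibbs energy.** Offsets {(1,0), (0,1), (1,1), (1,−1)} (the
8-neighbourhood up to symmetry), Q = 8 gray levels quantized uniformly
over the normalized scan's range. For each offset, the joint co-occurrence
distribution over cliques with *both* endpoints in the layer is compared
with the product of marginals; the marginal is computed over the
clique-endpoint multiset of that offset, which makes the symmetrized
marginalization of the joint reproduce it exactly. The potential scale ρ
cancels from the energy and is fixed at 1; the partition function is never
needed. The marker is the per-column-bin energy (10 bins), summarized by
the CDF descriptor; a scalar per-layer mode exists.

**GLCM.** Same Q and quantization pathway; both ordered directions of each
offset are counted (symmetric matrix), normalized to probabilities.
Contrast, correlation, energy and homogeneity follow the classical
definitions; correlation of a constant region (0/0) is defined as 0. GLCM
features are global per layer — no binning or CDF — and are scaled by
their training-fold maxima.

**Thickness.** The harmonic potential is solved by Jacobi iteration of
the 4-neighbour average with Dirichlet values 1 on the lower and 0 on the
upper boundary pixels (tolerance 1e-5 on the max update; the cap scales
with the squared band height; interior holes become reflecting
obstacles). Streamlines of −∇γ start at equal arc length along the lower
boundary (default 60 seeds) and advance by midpoint steps of 0.5 px with
bilinear gradients. Outside the domain the potential is continued by
signed linear extrapolation (nearest value ± distance × median interior
gradient) so that the bilinear zero contour passes through the
low-boundary pixel centres — without this the endpoint overshoots by
about half a pixel. Thickness is the Euclidean distance between the
streamline's endpoints (not its arc length), binned by start column. Flat
slabs are recovered exactly; 15–30° tilted slabs and annuli to well
within 2%.

**Tortuosity.** |κ| from the circumradius of (p−w, p, p+w) triples
(window w = 5 samples) along each boundary polyline taken at 1-px column
spacing, after a width-3 moving average that suppresses rasterization
staircase curvature. The layer marker concatenates the binned profiles of
its upper and lower boundaries (10 bins each). The window and smoothing
trade small-wavelength sensitivity for robustness: a sinusoid of
amplitude 5 px and wavelength 100 px is recovered within ~1% of
`a(2π/λ)²`.

**CDF descriptors.** The 10th–90th percentiles (linear interpolation
between order statistics — numpy's "linear" convention, fixed because the
downstream classifiers are sensitive to it). NaN sentinels (empty bins,
dropped offsets) are excluded; profiles with < 9 finite values are still
summarized, with a warning.

## Classifier

Per (layer, marker): features standardized on the training fold, linear
SVM (C = 1), sigmoid (Platt-style) probability calibration. The
probabilities that train the fusion networks are produced out-of-fold by
grouped 5-fold stacking within the training set, so no fusion input comes
from a model that saw the same scan. The final calibration uses those
out-of-fold decision values with a refitted SVM. The reflectivity feature
scalers (95%-CI upper bound mean + 1.96·SE per percentile, per layer;
GLCM per-feature maxima) are likewise fitted on training folds only and
frozen. Missing descriptors are imputed with training-fold medians.

Fusion networks are single-hidden-layer backpropagation nets (tanh
hidden, softmax output): 4 → 49 → 2 per layer, 12 → 30 → 2 globally;
full-batch gradient descent with momentum 0.9, learning rate 0.01, at
most 2000 epochs, stopping after 100 epochs without improvement beyond
1e-6. The global net is trained on the layer nets' outputs over the same
out-of-fold stage-1 probabilities (training the deeper stages on held-out
rather than resubstitution probabilities is this package's leakage-control
choice; both stages use the same out-of-fold base). Ties at probability
0.5 resolve to DR — the sensitive choice. Training is bit-reproducible
given (data, config, seed).

Evaluation is always subject-grouped: all scans of a subject share a
fold; K-fold assignment is class-stratified within ±1 subject; LOSO puts
one subject per fold. DR is the positive class. AUC is computed by
trapezoidal ROC over the global DR probability. A lineage audit object
records, per fold, that no test scan entered any training-fold fit.

## Synthetic phantoms

A phantom is twelve stacked bands between a dark vitreous and a mid-gray
choroid on a 160 × 256 grid (a desk-scale stand-in for clinical
1024-row scans; all geometry is parameterized in pixels, so nothing
depends on this size). Boundaries are smooth curves: a parabolic global
bow (amplitude 8 px) plus a Gaussian foveal pit (depth 45 px, width
80 px) that thins the inner five layers toward the centre, proportionally
to their thickness. Default layer thicknesses (12, 10, 10, 8, 7, 16, 3,
4, 4, 5, 4, 7 px) and reflectivities (170, 90, 120, 80, 115, 55, 110, 70,
190, 125, 145, 200 on the 8-bit scale, vitreous 10, choroid 60) give
OCT-like contrast ordering with every layer mean distinct.

Speckle is multiplicative unit-mean lognormal noise with fractional
standard deviation 0.08 (layer contrast-to-noise ≈ 3); an additive
Gaussian mode exists. DR scans apply per-layer thickness deltas
(INL +2 px, ONL +5 px), reflectivity deltas (NFL −12, GCL −6, ONL −8), a
sinusoidal displacement of all boundaries (amplitude 2 px, 4 cycles per
width — same phase everywhere, so ordering is preserved while every
boundary gains curvature), and *texture* perturbation: intra-retinal
noise scaled by 1.3 and spatially correlated (Gaussian-smoothed,
correlation length 1 px). The texture component exists because a
co-occurrence energy statistic measures spatial dependence: shifting only
the mean of independent speckle cannot move it in a consistent direction,
whereas diseased tissue plausibly shows clumped, heterogeneous
backscatter. Cohorts draw per-subject anatomy jitter (thickness ±10%,
reflectivity ±5 gray, pit ±10%, bow ±20%) from one master seed, with
per-scan seeds derived by a spawn-key counter, so identical seeds give
bit-identical cohorts.

What the phantoms do **not** emulate: physical speckle interference
statistics, vascular shadowing, motion/averaging artifacts, pathology
such as edema, 3-D geometry, and inter-device intensity scales. A passing
phantom suite therefore demonstrates that the pipeline recovers known
perturbations of the stated kinds under controlled noise — not clinical
performance.

## Numerical choices and degeneracies

- Quantization of normalized intensities uses the scan's own range; a
  constant region maps to level 0 and yields the analytic GLCM/MGRF
  limits (energy 1 / E = 0).
- Variance floor 0.25 gray² in EM; mixture responsibilities guarded by
  1e-300 floors.
- Jacobi stopping on the max update; non-convergence raises with the
  achieved residual rather than returning silently.
- Argmax label ties break toward the smaller label (innermost layer) via
  numpy argmax order.
- Streamlines abort (and the pair is skipped, with a warning) after
  4 × image-height of travel.
- `correlation = 0` for zero marginal variance; `κ = 0` for collinear or
  repeated points.
- A degenerate reference (|R12 − RV| < 1e-6 of the gray range) is an
  error, not a silent division.

## Problem sizes

Defaults used by the test suite and experiments: phantoms 160 × 256;
atlases of 4 entries; cohorts of 10–60 subjects with 1–2 scans each. The
end-to-end recovery experiment uses 60 subjects × 2 scans under LOSO with
marker-ablation baselines, all markers extracted from ground-truth label
maps (the segmentation stage is validated separately on its own scans,
since MAP segmentation of every cohort scan adds nothing to what the
Dice evaluation already establishes).

## Known limitations

- The segmentation intensity model assumes layers are distinguishable in
  gray value up to mixture overlap; it has no texture term of its own.
- Topology enforcement assumes single-valued, column-monotone boundaries
  on the warped grid (true for macular B-scans through the fovea, not for
  pathologies that fold layers).
- The adaptive shape prior interpolates only among atlas anatomy;
  out-of-family inputs degrade gracefully via the intensity term but are
  not detected as out-of-distribution.
- Platt calibration with few training subjects yields coarse
  probabilities; the fusion nets partially compensate.
- Thickness streamlines assume the layer is 4-connected between its
  boundaries; holes are treated as obstacles, which locally lengthens
  paths.
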