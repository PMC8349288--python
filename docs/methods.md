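# Methods

## Acquisition and motion model

The forward model is a centered, unitary 2-D DFT of a square, even-sided
image: spatial coordinates and integer frequencies both run over
`[-N/2, N/2)` with the DC sample at index `N/2`, and the transform uses
orthonormal scaling so Parseval's identity holds exactly and image- and
k-space energies are directly comparable. Array rows are phase-encode lines
(`k_y`), columns the frequency-encode axis (`k_x`).

Per-line translational motion is modelled as one shift pair
`(p(k_y), q(k_y))`, in pixel units, per acquired row: within a row the
readout is fast enough to freeze motion, between rows the object may move.
Corruption multiplies k-space by `exp(-i φ)` with
`φ(k_x, k_y) = 2π (k_x p(k_y) + k_y q(k_y)) / N` — the discrete shift
theorem in cycles-per-field-of-view units. Consequences used throughout:

* the k-space magnitude is exactly invariant under corruption;
* a constant trajectory is a pure circular shift of the image;
* corruption composes additively in the trajectories.

Shifts must stay below `N/4` pixels; beyond that, wrap-around makes the
inverse problem ill-posed, and the validation rejects rather than clips.

Trajectory families: `none`, `step` (abrupt position change at a chosen
fraction of the acquisition — a patient shifting once), `sinusoid`
(respiration-like periodic motion), `random_walk` (seeded cumulative Gaussian
drift), plus arbitrary per-line CSV input. Rotations, through-plane motion
and non-Cartesian sampling are out of scope.

## Phantoms

All phantoms are additive compositions of rotated ellipses with closed-form
geometry, rasterized on the centered grid: `disk` (radius `0.3·N`),
`ellipses` (three overlapping ellipses), `shepp_logan_like` (the classic
head-phantom ellipse table scaled by 0.43), and `pelvis_like` (a broad oval
cavity, two lateral organ-like ellipses, a midline body, and one
low-intensity inclusion mimicking a fluid collection). Every model keeps all
nonzero pixels at least 10% of the grid size away from each edge — a support
constraint is only informative when a real background exists.

Component intensities are fixed so that composed values stay in `(0, 1]` and
every component sits well above background (≥ 0.5 before intensity-range
mapping for the multi-ellipse model), which keeps a two-phase
piecewise-constant segmentation from absorbing dim components into the
background.

Noise is additive Gaussian in the image domain, applied after rasterization
and clipped at zero to preserve magnitude-image semantics. The clamp
half-rectifies background noise (its mean is biased by ≈ `0.4σ·√(2/π)`
there), so Gaussianity holds only where intensities are far from zero; tests
of the noise statistics therefore look at the object interior.

`true_support` returns the exact union of each model's ellipses dilated by a
2-pixel margin — the oracle region for simulation studies.

What the generator does **not** emulate: coil sensitivities, relaxation
(T1/T2) contrast, field inhomogeneity, partial-volume texture, and realistic
anatomy. Passing tests demonstrate the correction mathematics, not clinical
image quality.

## ROI extraction

Three deterministic extractors share one cleanup pipeline (3×3 morphological
closing, removal of components below a minimum area, dilation by a 2-pixel
safety margin — a support that hugs the object clips true signal and stalls
the correction):

* **Threshold**: binarize at a fractional intensity level,
  `min + q·(max − min)` with `q = 0.5` by default. The level-based rule
  (rather than an empirical intensity quantile) is deliberate: it is
  invariant to how much of the frame the object covers, whereas a median
  threshold on a mostly-background image selects the whole frame. For
  multi-tissue phantoms with dim compartments, lower `q` below the dimmest
  tissue fraction.
* **Active contour (snake)**: minimizes
  `E = Σ α|v_{i+1}−v_i|² + β|v_{i+1}−2v_i+v_{i−1}|² − Σ |∇(G_σ∗I)|²(v_i)`
  over a closed 200-vertex contour initialized on the threshold mask's
  boundary. Defaults `α = 0.1`, `β = 0.05`, `σ = 2 px` balance smoothness
  against edge attraction at the 128–256 px scales used here. The optimizer
  is full-contour gradient descent with backtracking: a step is accepted only
  if the total energy decreases, so the energy history is non-increasing by
  construction. (Greedy single-vertex search was rejected: moving one vertex
  alone always kinks the contour, and the bending penalty then blocks every
  move.) A collapsed or irreparably self-crossing contour falls back to the
  initial mask with a warning; shapely repairs mild self-intersections.
* **Level set**: region-based two-phase piecewise-constant evolution
  (morphological Chan–Vese) from a fixed checkerboard initialization; the
  phase with the higher mean magnitude becomes foreground (`invert` flips
  this for dark-on-bright objects). Chosen over edge-based level sets
  because it needs no edge map and is robust on noisy magnitude images.

Extraction from an already-corrupted reconstruction is the realistic use;
ghosts raise the background and can leak into any extractor's mask, which
weakens (but does not break) the subsequent correction.

## Correction loop

Given corrupted k-space `S'`, the loop alternates a support projection in
the image domain with magnitude replacement in k-space:

    g_j  = IFFT(G_j)                       (G_1 = S')
    g'_j = g_j · 1_R                       (zero outside the ROI)
    G'_j = FFT(g'_j)
    φ'_j = wrap(arg G'_j − arg G_j)
    G_{j+1} = exp(i · arg G'_j) · |S'|     (cumulative rule, default)

The cumulative rule is the classical error-reduction scheme: both steps are
projections onto closed constraint sets, so the support-violation energy
(the fraction of image energy outside `R`; total energy is conserved by
Parseval and the fixed magnitude) never increases. The alternative
`literal` rule, `G_{j+1} = exp(i φ'_j)·|S'|`, applies only the per-step
phase *difference*; it is exposed for experimentation but discards the
accumulated phase and does not in general converge to a support-consistent
image.

Numerical choices:

* **Stopping**: relative change of the support-violation energy `< tol`
  (default `1e-4`) between successive iterations, or `max_iter` (default
  50). The denominator is floored at `1e-15` so an already-satisfied
  constraint (violation energy at round-off level) counts as converged
  immediately instead of dividing by a denormal.
* **Phase of (near-)zero samples**: where either magnitude is below
  `1e-12`, `φ'` is defined as 0 — the phase of a zero sample carries no
  information and its `arg` is numerical noise.
* **Wrapping**: phases wrap to `(−π, π]`; no unwrapping is attempted, since
  the update applies `exp(iφ)` which is wrap-invariant.
* **ROI schedule**: the ROI is extracted once from the corrupted
  reconstruction and held fixed; per-iteration re-extraction is available
  (`refine_roi_each_iter`) but couples segmentation noise into the loop.
* The trajectory itself is never estimated; the method corrects the phase
  map, not the motion parameters.

The measured-magnitude constraint `|G_j| = |S'|` holds exactly at every
iterate by construction.

## Metrics

All comparisons use magnitude images. Because support + magnitude determine
the image only up to a global translation, `register_shift` finds the
integer circular shift (each component bounded by `N/4`) maximizing the
cross-correlation, with ties broken toward the smallest L1 shift and then
lexicographically; integer-only registration is deliberate — subpixel
alignment would hide genuine error. `nrmse` is the registered L2 magnitude
difference over the reference norm; `ghost_ratio` is the fraction of image
energy outside the *true* support (0 for a clean image, 1 for pure ghosts).
The end-to-end report carries both metrics before and after correction plus
the relative NRMSE reduction.

On the package's standard scenario — 128×128 disk phantom, step motion of
4 px at half acquisition along x, oracle ROI, cumulative rule — the
correction is expected to reduce registered NRMSE by at least 30% within 50
iterations; this bar is calibrated on that scenario and is a property of the
artifact, not a clinically validated threshold.

## Problem sizes

Default simulation geometry is 256×256 (a common acquisition matrix); the
test suite and the standard scenario use 128×128, where one correction run
(50 iterations, two 128² FFTs each) takes well under a second and the
brute-force DFT oracle is evaluated at 4–16 px. These sizes were chosen so
the full suite exercises every path in seconds while remaining comfortably
above the regime where rasterization artifacts would dominate.

## Known limitations

* Translational, in-plane, per-line-constant motion only; rotations mix
  k-space magnitudes and are outside the model.
* A pure drift (random-walk) trajectory has a large uncorrectable component:
  the loop recovers phase consistency up to a global shift, and what looks
  like drift-induced blurring may survive. Observed reductions across
  random-walk seeds range from ≈0% to ≈40%.
* Convergence of error-reduction iterations stagnates; the loop typically
  exhausts `max_iter` rather than meeting `tol` on corrupted inputs.
  Acceleration schemes (e.g. hybrid input–output updates) are not
  implemented.
* ROI quality bounds correction quality: a support mask that excludes true
  signal removes it from the reconstruction permanently.
* All validation is on analytic phantoms; no claim is made about clinical
  images.
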