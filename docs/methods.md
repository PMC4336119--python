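# Methods

This note documents the models implemented in `thynseg`, the parameters
that matter, the numerical conventions, and the design decisions taken
where the method description left genuine freedom. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Intensity conventions

All stages operate on 2-D `float64` rasters with intensities in [0, 1]
("gray images"); 8-bit quantization happens only at file I/O. Coordinates
are row-major and 0-based. RGB inputs collapse to Rec. 601 luminance.
Images entering the pipeline must be at least 8 px on each side.

## Homomorphic filtering

The filter computes `exp(F⁻¹[H · F[log(img + ε)]]) − ε` with the Gaussian
high-emphasis transfer

    H(D) = (γ_H − γ_L) · (1 − exp(−s·D²/D0²)) + γ_L,

where D is the radial frequency in cycles across the image. The output is
affinely rescaled onto [0, 1]; a constant (zero-range) result maps to all
zeros by convention, which avoids a 0/0 in the rescale and is asserted in
the tests.

Defaults: γ_L = 0.9, γ_H = 1.0, D0 = 4 cycles, s = 1, ε = 1e-3. Two
considerations drive these values rather than the textbook-style
γ_L = 0.5 / γ_H = 1.5 / D0 = 30:

* **A high-frequency boost amplifies speckle.** Speckle occupies exactly
  the band that γ_H > 1 would amplify, handing the diffusion stage a worse
  image than it received. With γ_H = 1 the filter only compresses the
  illumination component.
* **D0 must sit below the anatomical scale.** On a 128-px crop the regions
  of interest live at roughly 3–10 cycles; a 30-cycle knee treats the
  regional structure itself as "illumination" and compresses the very
  contrast the segmentation needs. D0 = 4 targets the slow depth-gain /
  illumination field only.

On phantoms, which have no illumination artifact, the stage is nearly
neutral by design; on clinical scans with depth-gain variation γ_L can be
lowered. The transform uses the plain FFT of the image (periodic, no
padding); residual ringing is damped by the diffusion stage.

## Edge-enhancing anisotropic diffusion

The evolving image u follows one explicit Euler step per iteration:

    u ← clip( u + Δt·[ f1·u_MM + f2·u_NN − f3·tanh(l·255·v_MM)·|∇u| ], 0, 1 )

with M the unit gradient direction, N its perpendicular, and v = G_σ ∗ u a
Gaussian-smoothed copy recomputed from the current iterate each step.
Derivatives are central differences with reflective (mirror) boundaries.

### Coefficient forms

The stopping functions ship in the exponential Perona–Malik form

    f1 = exp(−(|∇u|/a)²),      f2 = exp(−(|∇u|/(a·b))²),

with the rational form `1/(1+(·)²)` selectable via
`DiffusionParams(form="rational")`. The exponential form is the default
because at the reference gradient scale a = 0.15 the rational form decays
too slowly: realistic edge gradients (0.2–0.4 per px) keep 10–40 % of the
diffusive flux flowing across the edge, which over n = 50 iterations erodes
the region contrast the downstream graph cut depends on. The exponential
form shuts flux off sharply at edges (e.g. f1 ≈ 2·10⁻³ at |∇u| = 0.38)
while leaving speckle-scale gradients (≈ 0.05–0.08) freely smoothed. Both
forms satisfy f1 ≤ f2 pointwise for b ≥ 1 and reduce to linear diffusion
as a → ∞.

The enhancement gain is implemented as a smooth **edge-area gate**

    f3 = 1 − exp(−(|∇v|/c)²),

reading c as the gradient threshold of the smoothed image above which a
pixel counts as edge area (c = 0.015 ≈ 4 gray levels of 255): f3 is 0 in
flat regions, saturates at 1 on edges. The tanh argument converts v_MM to
8-bit gray units (×255), the scale on which the small slope constant
l = 0.015 produces a gentle, sign-correct shock response
(tanh(l·255·v_MM) ≈ ±0.1–0.3 at edge shoulders). With both factors the
sharpening term balances the diffusive tail erosion of ramps, which is its
purpose: moving intensity away from the inflection of v narrows edges
instead of blurring them. Composing the same constants against [0,1]-scale
magnitudes would make the term O(10⁻⁶) — functionally absent — so this
scale convention is load-bearing and is regression-tested via the
edge-width bound below.

### Parameters

| name | meaning | default |
|------|---------|---------|
| `dt` | Euler step (stability cap 0.5) | 0.1 |
| `n_iters` | iterations | 50 |
| `a` | gradient scale: edges above it are preserved | 0.15 |
| `b` | tangent/gradient anisotropy ratio (≥ 1 smooths along structures) | 1.4 |
| `c` | edge-area gradient threshold of the smoothed image | 0.015 |
| `l` | tanh slope (per 8-bit gray unit of v_MM) | 0.015 |
| `smooth_sigma` | Gaussian scale of v, px | 0.7 |
| `form` | stopping-function shape | `"exp"` |

`smooth_sigma = 0.7` rather than a full pixel: v steers the shock term, and
a broader v tracks a blurred version of the boundary, leaving a halo of
mixed intensities around dark structures; 0.7 px keeps the sharpening
centered on the true edge while still denoising v_MM.

### Numerics

* u_NN is computed from the exact trace identity u_MM + u_NN = Δu, so the
  isotropic limit (f1 = f2 = 1, c = 0) matches an independent explicit
  heat-equation loop to machine precision — this is asserted at 1e-10.
* Where the gradient vanishes exactly (e.g. the four corners under mirror
  padding) the M–N frame is undefined; the rotationally symmetric
  convention u_MM = u_NN = Δu/2 is used.
* A constant image is an exact fixed point for every parameter setting.
* Each step clips to [0, 1]; the explicit scheme is used with the stated
  Δt range, guarded by the Δt ≤ 0.5 invariant.

## Fractional-differential gradient

Grünwald–Letnikov weights `c_0 = 1, c_k = c_{k−1}(k−1−v)/k` are laid
symmetrically outward from the center along the x, y and both diagonal
directions of an odd `support × support` mask; the two arms share the
center sample, so the center coefficient is 2. The mask sum 2·Σc_k is
nonzero for 0 < v < 1 — the property that preserves low-frequency texture —
and v = 1 is rejected (sum exactly 0, a plain second difference). The image
response convolves with all four masks (reflective boundaries), takes the
per-pixel maximum, and clips negatives to 0; the mask set is closed under
90° rotation, making the response rotation-equivariant to round-off.
Stacking subtracts the locally-constant baseline (mask sum × pixel value)
so flat regions are invariant:

    enhanced = clip(img + λ·(response − mask_sum·img), 0, 1).

Defaults: v = 0.5, support 5, λ = 1. A compact alternative operator
(3×3, center 8, ring of −v, sum 8−8v) is available as `variant="table1"`.

## Normalized-cut engine

* **Affinity.** W_ij as in the README, with F in [0, 1] and pixel
  coordinates normalized by max(height, width) so σ_X = 0.1 is meaningful
  against a radius r = 20 raw pixels. Exponents use the squared-scale (σ²)
  convention. W_ii = 1 (a pixel is maximally similar to itself) and the
  self-loops are included in degrees and associations — this follows from
  the weight function at zero distance and pins down all Ncut values; the
  2-node closed form w/(w+1) + w/(w+1) is the regression anchor.
* **Graph construction** enumerates integer offsets within the radius and
  assembles one sparse symmetric matrix (≈ 18 M nonzeros at 128² with
  r = 20); images above 16384 px are rejected with advice to downscale.
* **Eigensolver.** The generalized problem (D − W) y = λ D y is solved via
  the symmetrically normalized Laplacian: dense `eigh` below 1200 nodes, a
  Lanczos iteration (`eigsh` on 2I − L_sym, deterministic all-ones start
  vector) above. Eigenvectors map back as y = D^{−1/2} z and are
  sign-fixed (first nonzero entry positive), so runs are reproducible.
* **Discretization.** Candidate thresholds are 32 evenly spaced quantiles
  of the eigenvector **plus the midpoints of its 32 largest sorted-value
  gaps**. The quantile grid alone straddles the value gap that isolates a
  region holding a few percent of the pixels (a 5 %-area structure falls
  between the 3 % quantile steps); the gap midpoints recover exactly those
  splits, including the component split of a disconnected graph. The
  bipartition with the minimal true Ncut wins; ties break toward the more
  balanced split, then the lower threshold.
* **Which eigenvectors.** Each split searches the 4 smallest non-trivial
  eigenvectors and keeps the best discretized split. The Fiedler vector of
  a large uniform region is often a smooth spatial mode — cheap in the
  continuous relaxation, expensive after thresholding — while the compact
  salient structure (a nodule) appears in eigenvector 2–4; measured on the
  clean phantom, the nodule split (Ncut 0.035) lives in eigenvector 3
  while every threshold of the Fiedler vector costs ≥ 0.074.
* **Recursion.** The graph is built once; sub-regions use the restriction
  of W with degrees recomputed. Largest region first; disconnected regions
  split along components (Ncut exactly 0); a split is accepted while its
  Ncut < 0.065, the region count stays below `max_regions` (10) and both
  sides keep ≥ 16 px (the small-region degeneracy guard). Final labels are
  ordered by descending region size.

## Synthetic phantom

The generator renders a piecewise-constant scene — parenchyma 0.7, an
elliptical hypoechoic nodule 0.2, a near-anechoic trachea 0.05 — multiplies
it by L-look fully developed speckle (per-pixel mean-1 Gamma variates of
shape L), blurs with an isotropic Gaussian PSF, and clips to [0, 1]. Labels
(0 background, 1 nodule, 2 trachea) are returned alongside. Output is fully
determined by the integer seed.

Default study conditions: 128×128, L = 20 looks (coefficient of variation
≈ 22 %), PSF σ = 0.6 px, nodule ellipse centered at (52, 56) with semi-axes
(16, 20) rotated 20°, trachea at (94, 82) with semi-axes (10, 13). The
defaults sit inside a feasibility region pinned from three sides:

* the gray histogram must concentrate in a narrow band around the
  parenchyma level (≥ 80 % of pixels within ±0.15), emulating the low
  dynamic range of clinical crops — this bounds the speckle strength and
  PSF from one side;
* plain normalized cut on the raw phantom must *fail* (otherwise the
  enhancement stages would have nothing to demonstrate) — this bounds the
  speckle from the other side;
* the true region splits of the clean phantom must cost less than the
  0.065 stopping threshold, or no pipeline could ever recover them — this
  bounds the PSF (at σ = 1.0 px the clean nodule split already costs
  0.078) and requires structures to keep wide parenchyma corridors to the
  frame border (an ellipse near the border creates a narrow corridor whose
  cut is cheaper than the threshold, fragmenting the background).

What the phantom does **not** emulate: depth-dependent gain and focus,
anisotropic PSF (axial ≠ lateral resolution), shadowing/enhancement
artifacts behind structures, tissue texture inside the nodule, curved-probe
geometry, and the spatial correlation of real speckle. Passing the phantom
tests therefore demonstrates the pipeline's behavior under idealized
multiplicative noise, not clinical performance.

`dice(A, B) = 2|A∩B|/(|A|+|B|)` (1.0 for two empty masks) scores masks;
`evaluate` matches predicted to truth labels greedily by pixel overlap, so
label permutations score identically.

## Pipeline and problem sizes

Stage order is fixed (homomorphic → diffusion → fractional → Ncut); each
stage has a skip flag, and skipping all three enhancement stages is the
Ncut-only ablation used as the baseline. The graph is built on the
fractionally enhanced image by default (`ncut.feature: raw` switches to the
pipeline input). Configuration round-trips through flat two-level YAML.

The shipped tests and the acceptance script run at the native study scale —
128×128 phantoms (16 384-node graphs) for segmentation, 64×64 rasters for
the diffusion statistics, and 6–12-node graphs for the exhaustive Ncut
oracle (2^(n−1) − 1 bipartitions enumerated per graph) — sizes chosen so
the whole suite completes in minutes on a single CPU.

## Known limitations

* The diffusion coefficient forms are an interpretation: the printed
  originals are not recoverable, only the roles of a, b, c, l. The forms
  are isolated behind `diffusion_coefficients` so alternates can be
  swapped; the rational variant is provided.
* The homomorphic transfer constants are package choices (see above), not
  reference values; none are stated for the method.
* The fractional order v used originally is unknown; v = 0.5 is the
  package default and both mask variants are shipped.
* Whether the 0.065 threshold applies per split or globally is unstated;
  per-split is implemented.
* Images above 16 384 px require cropping or downscaling — no Nyström or
  multiscale approximation is provided.
* Eigenvector computations on near-degenerate spectra (λ₂ ≈ λ₃) can mix
  modes; the multi-eigenvector split search makes the recursion robust to
  this, but individual Fiedler vectors may vary between platforms at the
  1e-8 level.
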