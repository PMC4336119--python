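# thynseg

Segmentation of thyroid-nodule B-mode ultrasound images by an improved
normalized cut: speckle-aware preprocessing (homomorphic filtering,
edge-enhancing anisotropic diffusion, fractional-differential gradient
enhancement) followed by recursive spectral graph partitioning.

## Who this is for

B-mode thyroid scans are hard to segment automatically: coherent speckle
corrupts every region, the gray dynamic range is narrow, and nodule
boundaries are weak. Yet delineating the nodule and the trachea is exactly
what guides fine-needle aspiration. `thynseg` implements a graph-based
segmentation pipeline built for these conditions, together with a synthetic
phantom generator so that every stage — and the end-to-end behavior — is
testable without clinical data.

## The method

Pixels form a weighted graph G = (V, E, W) with affinities combining gray
similarity and spatial proximity,

    W_ij = exp(−(F_i − F_j)² / σ_I²) · exp(−‖X_i − X_j‖² / σ_X²)   for ‖X_i − X_j‖ ≤ r,

zero beyond radius r. A bipartition (A, B) is scored by the normalized cut

    Ncut(A, B) = cut(A,B)/assoc(A,V) + cut(A,B)/assoc(B,V),

whose relaxation is the generalized eigenproblem (D − W) y = λ D y. Each
region is recursively split along the best threshold of the smallest
non-trivial eigenvectors until no split scores below the Ncut threshold.
Unlike the minimum cut, this criterion does not chip off isolated specks —
the property that makes it suitable for anatomical regions.

Plain Ncut fails on raw speckle, so three enhancement stages run first:

1. **Homomorphic filter** — log-domain radial high-emphasis transfer
   compressing the slow illumination field while leaving detail intact.
2. **Anisotropic diffusion** — a PDE in the local gradient/tangent frame,
   `u_t = f1·u_MM + f2·u_NN − f3·tanh(l·v_MM)·|∇u|`, smoothing speckle in
   flat areas, diffusing along (not across) structures, and actively
   sharpening edges through the hyperbolic-tangent shock term driven by the
   Gaussian-smoothed image v.
3. **Fractional-differential gradient** — Grünwald–Letnikov masks in four
   directions, fused by per-pixel maximum and stacked onto the image; a
   fractional order keeps low-frequency texture (nonzero mask sum) while
   boosting high-frequency detail.

Shipped defaults follow the reference parameter set: Δt = 0.1 (valid range
0.06–0.3), n = 50 iterations, (a, b, c, l) = (0.15, 1.4, 0.015, 0.015),
Ncut threshold 0.065, σ_X = 0.1, σ_I = 0.3, r = 20 px. See
`docs/methods.md` for what each parameter does and for the interpretation
choices behind the diffusion coefficients.

## Worked example

Segment the default synthetic phantom (128×128, parenchyma 0.7, hypoechoic
nodule 0.2, trachea 0.05, 20-look speckle):

```python
from thynseg import PhantomSpec, PipelineConfig, run_pipeline
from thynseg.pipeline import evaluate

run = run_pipeline(PhantomSpec(seed=0), PipelineConfig())
seg = run.segmentation
print(f"regions: {seg.n_regions}")
print("accepted ncuts:", ", ".join(f"{v:.4f}" for v in seg.split_ncuts))
for lab in range(seg.n_regions):
    m = seg.labels == lab
    print(f"label {lab}: {int(m.sum())} px, mean gray {run.input_image[m].mean():.3f}")
for row in evaluate(seg.labels, run.truth):
    print(row)
```

prints

```
regions: 3
accepted ncuts: 0.0048, 0.0496
label 0: 14990 px, mean gray 0.700
label 1: 995 px, mean gray 0.209
label 2: 399 px, mean gray 0.072
{'truth': 0, 'pred': 0, 'dice': 0.9993992390361124, 'matched': True}
{'truth': 1, 'pred': 1, 'dice': 0.9930139720558883, 'matched': True}
{'truth': 2, 'pred': 2, 'dice': 0.9950124688279302, 'matched': True}
```

Both accepted splits score well below the 0.065 stopping threshold; the
three recovered regions match the ground-truth parenchyma, nodule and
trachea masks with Dice ≥ 0.99. Running the same phantom through the
normalized cut alone (all enhancement stages skipped) misses the nodule
entirely — the enhancement stages are what make the nodule separable.

The same pipeline is available from the shell:

```bash
thynseg phantom --out ph --seed 0          # phantom.png + mask.png + spec.yaml
thynseg run ph/spec.yaml --out out --dump-intermediates
thynseg eval out/labels.png ph/mask.png
```

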