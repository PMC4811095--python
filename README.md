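# patchtgv

Compressed-sensing MRI reconstruction that combines an **adaptively learned
patch dictionary** (K-SVD / orthogonal matching pursuit) with **second-order
total generalized variation** (TGV²), solved by ADMM with a closed-form,
FFT-diagonalized image update.

## The problem

MRI acquires data in k-space (the 2D Fourier domain of the image); scan time
is proportional to the number of k-space samples. Undersampling accelerates
the scan but makes the inverse problem ill-posed: the zero-filled inverse
DFT of the measured samples is corrupted by aliasing. Reconstruction
therefore needs prior knowledge. Two complementary priors are used here:

* a **patch-sparsity prior** — every small image patch has a sparse
  representation in a dictionary *learned from the image itself*, which
  captures fine structure and detail;
* a **TGV² prior** — the image is close to piecewise affine, which
  suppresses aliasing and noise in smooth regions without the staircase
  artifacts of plain total variation.

## The model

With `u ∈ ℂ^{n×n}` the image, `b = Ku + ξ` the noisy undersampled k-space
data (`K = PF`, `P` a sampling mask, `F` the unitary 2D DFT), `R` the
(overlapping, wrap-around) patch-extraction operator, `A` the dictionary and
`Γ` the sparse codes, the reconstruction solves

```
min_{u, p, A, Γ}  β/2 ‖Ku − b‖² + λ₀/2 ‖AΓ − Ru‖²
                  + α₁ ‖∇u − p‖₁ + α₀ ‖ε(p)‖₁
s.t.              ‖Γ_i‖₀ ≤ τ per patch,
```

where `p` is the auxiliary vector field of TGV² and `ε(p)` its symmetrized
gradient. The solver alternates

1. **dictionary learning** on patches of the current image (OMP sparse
   coding + K-SVD atom updates), and
2. **ADMM sweeps**: pixel-wise shrinkage of the two L1 splittings, a
   closed-form `(u, p)` update — the 3×3 block normal equations are
   circulant except for `K*K`, so after an FFT they decouple into one 3×3
   Hermitian solve per frequency (Cramer's rule) — and dual ascent.

Quality is measured by PSNR and HFEN (the relative norm of the
Laplacian-of-Gaussian-filtered error, sensitive to edges and fine features).

## Worked example

```python
import patchtgv as pt

truth = pt.shepp_logan(128)                       # phantom, range [0, 255]
model = pt.ReconstructionModel.from_image(
    truth, scheme="radial", factor=4, sigma=0.0, seed=0)
result = model.fit()
print(result.summary())
```

prints (timings aside):

```
Patch-dictionary + TGV reconstruction
==============================================
grid                 128 x 128
sampling scheme      radial
undersampling factor 3.99
noise sigma          0
beta (resolved)      1e+06
lambda0/alpha1/alpha0 0.9 / 0.0001 / 1e-06
iterations run       150 (max iters)
final objective      9.02067e+06
PSNR (zero-filled)   19.21 dB
PSNR (reconstruction) 26.82 dB
HFEN (reconstruction) 0.0877
```

i.e. at 4-fold pseudo-radial undersampling the joint model improves on the
zero-filled baseline by ~7.6 dB and reduces the high-frequency error norm
to 0.09. `result.history` is a per-iteration DataFrame (objective, data
residual, primal residuals, PSNR); `result.plot_images()` and
`result.plot_history()` visualize the reconstruction and convergence.

The same pipeline is available from the shell:

```sh
patchtgv simulate --n 128 --scheme radial --factor 4 --out k.h5
patchtgv reconstruct --kspace k.h5 --reference k.reference.npy --out rec.npy
patchtgv sweep --schemes radial,random2d --factors 4,8 --sigmas 0 --out table.csv
```

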