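# Methods

## Measurement model and conventions

The image `u` lives on an n×n grid with intensities nominally in [0, 255]
(complex-valued in general; the phantom generators scale to this range).
The acquisition operator is `K = PF` with `F` the **unitary** 2D DFT and DC
stored at array index (0, 0); `P` selects the sampled k-space locations.
Unitarity makes `K*K` an orthogonal projector and, together with the other
conventions below, renders every block of the image update diagonal in the
DFT basis. Measurement noise is complex white Gaussian with standard
deviation σ per real/imaginary channel, on the same (unitary-DFT) scale as
the k-space values; σ values quoted in this package assume the [0, 255]
intensity convention.

Sampling masks: pseudo-radial (L equiangular lines through the centre,
nearest-grid-point rasterized, L chosen by search so the achieved factor is
closest to the target), variable-density 2D random (fully kept central
disk, selection probability decaying with k-space radius, exact sample
count), Cartesian random phase-encode (full rows: a central band plus
random rows), and a single-shot Archimedean spiral whose pitch is bisected
to the target factor. All generators are pure functions of
(scheme, n, factor, seed), always keep DC, and raise if the achieved factor
misses the target by more than 15%.

## Patch system

Patches are b×b blocks (default b = 6, so M = 36 pixels) at **stride 1
with periodic wrap-around**. This makes the patch normal operator exactly
`RᵀR = M·I`, which is what keeps the image update solvable in closed form;
with non-overlapping or non-wrapping patches the DL term would not be
diagonal in the DFT basis and the spectral solve would break near borders.
Patch origins and within-patch pixels are ordered row-major.

## Dictionary learning

The dictionary `A ∈ ℂ^{M×J}` (default J = 4M = 144 atoms) is initialized
as an overcomplete 2D-DCT (Kronecker product of 1D overcomplete DCT
frames, unit-norm columns; the first atom is flat and absorbs patch means,
so means are not removed before coding). Data are handled natively over ℂ:
OMP uses conjugate (Hermitian) correlations and K-SVD a complex rank-1
factor. Splitting real and imaginary parts would double M and silently
change the model for complex-valued scans.

Sparse coding is batch OMP with two stopping rules per patch: a hard cap
of τ = 7 nonzeros, and an error budget — coding stops once the residual
norm falls below the budget. The budget is the important part for
reconstruction: fitting every patch exactly would reproduce the aliasing
artifacts the prior is supposed to remove. The solver uses a
**continuation schedule**: the budget starts at `0.4 · rms(zero-filled) ·
√M` (a proxy for the aliasing level of the initialization), decays by 0.9
per outer iteration, and is floored at 1.15× the per-pixel noise std
propagated from k-space (`σ√(2Q)/n`, the usual dictionary-denoising
margin). Early iterations therefore code coarsely and discard artifacts;
later ones recover detail.

The K-SVD sweep updates each atom and its nonzero code row by the leading
singular pair of the restricted residual (computed exactly from the M×M
Hermitian Gram of the residual); atoms used by no patch are replaced by the
worst-represented patch. The sweep never increases the Frobenius fit.
Between alternations, near-duplicate atoms (coherence > 0.99) and atoms
coding fewer than 4 patches are likewise replaced by worst-represented
patches — the canonical dictionary cleanup, needed to escape local minima
in which one atom serves two distinct features. Because greedy OMP
re-coding can transiently worsen the fit, the learner tracks and returns
the **best iterate** seen; the reported error trajectory is the running
best and is therefore non-increasing by construction. On planted-dictionary
data (16-dim patches, 20 atoms, 3-sparse codes, 2000 samples, 30
alternations) this recovers ≥ 80% of atoms at |correlation| > 0.99 across
seeds; without the cleanup roughly half the seeds stall near 55–90%.

λ₀ weighs the dictionary-fit term only in the image update; inside the DL
alternation the sparsity constraint replaces any L1 code penalty, so the
code-penalty weight is reported as zero in the objective.

## TGV² calculus

Gradients are periodic forward differences (D1 along x/axis 1, D2 along
y/axis 0). The symmetrized gradient of a vector field p is the per-pixel
symmetric 2×2 matrix [[D1p1, (D2p1+D1p2)/2], [(D2p1+D1p2)/2, D2p2]],
stored as three planes with the off-diagonal entry once; all tensor inner
products and the Frobenius norm count it twice. Both shrinkage operators
are positive-part isotropic soft-thresholds — the proximal maps of the
corresponding L1 terms (verified against numeric minimization); for
complex fields they threshold the modulus and preserve phase.

## ADMM solver

Auxiliary variables y = Du − p and z = ε(p) carry the two L1 terms; their
updates are the pixel-wise shrinkages with thresholds 1/μ₂ and 1/μ₃. The
(u, p) subproblem is the quadratic

    λ₀/2 ‖AΓ − Ru‖² + β/2 ‖Ku − b‖²
    + α₁μ₂/2 ‖y − Du + p − ỹ‖² + α₀μ₃/2 ‖z − ε(p) − z̃‖²_w

whose normal equations were **re-derived from this quadratic** (the
implementation is validated against a dense direct solve assembled
independently from the primitive operators, at ≤ 1e−8 relative residual on
random instances; in practice it agrees to ~1e−15). All blocks are
circulant except `K*K`, which is diagonal in the DFT basis, so the system
decouples into an independent 3×3 Hermitian solve per frequency, done
vectorized by Cramer's rule. Degenerate configurations are handled
explicitly: with α₁ = α₀ = 0 the p-field drops out and u solves a scalar
spectral equation (p is returned as 0, the minimum-norm choice); the
determinant is floored at 1e−300 and a genuine singularity with positive
β/λ₀ raises an error.

Dual ascent uses the scaled form with step μ (default 1, the standard
choice).

### Parameters

| parameter | default | meaning |
|---|---|---|
| β | 1e6 (noiseless) or 1e6/σ² | k-space fidelity weight; effectively pins sampled frequencies when noiseless |
| λ₀ | 0.9 | dictionary-fit weight (`λ₀·M` enters the u-update) |
| α₁, α₀ | 1e−4, 1e−6 | TGV weights (nominal operating point of the method) |
| μ₂, μ₃ | 0.02 | splitting penalties; thresholds 1/μ = 50 intensity units |
| μ | 1 | dual step |
| outer / inner iters | 15 / 10 | DL–ADMM alternations / ADMM sweeps each |
| τ | 7 | OMP sparsity cap per 36-pixel patch |
| K-SVD iters | 5 | coding/update alternations per outer iteration |

The ADMM fixed point does not depend on μ₂/μ₃, only convergence speed
does. The defaults put the shrink thresholds at a sizeable fraction of the
intensity range, which converges fast for piecewise-smooth content and in
particular makes the pure-TGV degenerate mode (λ₀ = 0) practical; at the
nominal tiny α values the full model is insensitive to this choice. K-SVD
iterations per outer pass are kept at 5 because the dictionary warm-starts
from the previous outer iteration, so longer inner learning changes
nothing measurable while doubling runtime.

## Synthetic data

The Shepp–Logan head phantom (the standard 10-ellipse analytic
definition, scaled to [0, 255], any resolution) stands in for scanner
images; a complex-valued variant multiplies its magnitude by a smooth
random quadratic phase field, emulating the phase roll of real
acquisitions. These phantoms are piecewise constant with sparse edges —
favourable for both priors — and contain no texture, anatomy-scale
structure, receive-coil shading or physiological noise. Passing tests on
them validates the operators, the solver and the qualitative behaviour of
the priors; they do not predict absolute PSNR on in-vivo data.

Reported experiments use 128×128 phantoms (and 512 grids for mask
statistics); the noise-robustness comparison runs 6 outer iterations per
reconstruction, enough for a stable ordering across noise levels.

## Known limitations

* Single-coil, Cartesian-grid sampling only; no NUFFT/gridding for true
  non-Cartesian trajectories (the radial/spiral masks are rasterized onto
  the grid).
* The (u, p) closed form requires stride-1 wrap-around patches.
* The primal residuals of the two splittings decay roughly like O(1/k):
  about two to three orders of magnitude over 200 inner iterations on the
  64×64 phantom problem — adequate here, but a preconditioned or adaptive-μ
  scheme would converge tighter.
* The coding-budget continuation is a heuristic tied to the zero-filled
  artifact level; grossly misestimating it (e.g. for data far outside the
  [0, 255] convention) degrades the first iterations, though β and the
  budget can both be set explicitly.
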