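"""Joint dictionary + TGV reconstruction by ADMM.

The reconstruction model minimizes, over the image u, the auxiliary vector
field p, the dictionary A and the sparse codes Gamma,

    (beta/2) ||K u - b||^2  +  (lambda0/2) ||A Gamma - R u||^2
        +  alpha1 ||D u - p||_1  +  alpha0 ||eps(p)||_1,

subject to the per-patch sparsity cap on Gamma enforced by OMP.  K = P F is
the undersampled unitary Fourier operator, R the (stride-1, wrap-around)
patch extractor, D the periodic forward-difference gradient and eps the
symmetrized gradient.  Splitting y = Du - p and z = eps(p) turns both L1
terms into pixel-wise shrinkages; the remaining (u, p) subproblem is an
augmented-Lagrangian quadratic

    (lambda0/2)||A Gamma - R u||^2 + (beta/2)||K u - b||^2
      + (alpha1 mu2 / 2)||y - Du + p - yt||^2
      + (alpha0 mu3 / 2)||z - eps(p) - zt||^2_w          (w: z3 counted twice)

whose normal equations form a 3x3 block system in (u, p1, p2).  Every block
is circulant except K*K, which is diagonal in the DFT basis, so after a 2D
FFT the system decouples into an independent 3x3 Hermitian solve per
frequency, done in closed form by Cramer's rule.  The outer loop alternates
the dictionary-learning step (on patches of the current image) with a few
of these ADMM sweeps plus dual ascent.

The module follows the model/results idiom: build a
:class:`ReconstructionModel` from measured (or simulated) k-space, call
``fit()``, and read estimates and diagnostics off the returned
:class:`ReconstructionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dictlearn, metrics, patches, sampling, tgv
from .dictlearn import DLParams
from .patches import PatchConfig
from .sampling import KSpaceData, SamplingMask

__all__ = [
    "SolverParams", "ADMMState", "ReconstructionModel", "ReconstructionResults",
    "update_y", "update_z", "solve_up", "update_duals", "objective",
    "reconstruct",
]


@dataclass
class SolverParams:
    """Weights and iteration controls for the ADMM reconstruction.

    beta : k-space data-fidelity weight.  ``None`` resolves to 1e6 for
        noiseless data and 1e6 / sigma^2 when the measurement carries noise
        of per-channel std sigma (so fidelity relaxes as noise grows).
    lambda0 : weight of the dictionary fit ||A Gamma - R u||^2.
    alpha1, alpha0 : TGV weights on ||Du - p||_1 and ||eps(p)||_1.
    mu2, mu3 : penalty parameters of the y and z splittings; the shrinkage
        thresholds are 1/mu2 and 1/mu3 on the image intensity scale
        (nominally [0, 255]).  The ADMM fixed point does not depend on
        them, only the convergence speed does; the defaults put the
        thresholds at a sizeable fraction of the intensity range, which
        converges fast for piecewise-smooth content.
    mu : dual ascent step.
    outer_iters : dictionary-learning / ADMM alternations.
    admm_iters : inner y, z, (u, p), dual sweeps per outer iteration.
    tol : early stop when the relative change of u falls below this.
    code_err0 : initial per-patch sparse-coding error budget (absolute,
        intensity units per patch vector).  ``None`` resolves to
        ``0.4 * rms(zero-filled) * sqrt(patch_len)``, a proxy for the
        aliasing level.  The budget shrinks geometrically by
        ``code_err_decay`` each outer iteration (a continuation schedule:
        early iterations code coarsely and discard artifacts, later ones
        recover detail) and never drops below the measurement-noise floor.
    code_err_decay : geometric decay of the coding budget per outer
        iteration.
    """

    beta: float | None = None
    lambda0: float = 0.9
    alpha1: float = 1e-4
    alpha0: float = 1e-6
    mu2: float = 0.02
    mu3: float = 0.02
    mu: float = 1.0
    outer_iters: int = 15
    admm_iters: int = 10
    tol: float = 1e-4
    code_err0: float | None = None
    code_err_decay: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lambda0 < 0 or self.alpha0 < 0 or self.alpha1 < 0:
            raise ValueError("lambda0, alpha0, alpha1 must be non-negative")
        if min(self.mu2, self.mu3) <= 0 or self.mu < 0:
            raise ValueError("mu2, mu3 must be positive; mu non-negative")

    def resolved_beta(self, sigma: float) -> float:
        if self.beta is not None:
            return self.beta
        return 1e6 if sigma <= 0 else 1e6 / sigma ** 2


@dataclass
class ADMMState:
    """All per-iteration variables of the splitting."""

    u: np.ndarray                       # image, (n, n) complex
    p: np.ndarray                       # vector field, (2, n, n)
    y: np.ndarray                       # auxiliary for Du - p, (2, n, n)
    z: np.ndarray                       # auxiliary for eps(p), (3, n, n)
    y_dual: np.ndarray                  # scaled dual of the y split
    z_dual: np.ndarray                  # scaled dual of the z split
    A: np.ndarray | None = None         # dictionary (M, J)
    codes: np.ndarray | None = None     # sparse codes (J, I)

    @classmethod
    def initial(cls, u0: np.ndarray) -> "ADMMState":
        n = u0.shape[0]
        zeros2 = np.zeros((2, n, n), dtype=np.complex128)
        zeros3 = np.zeros((3, n, n), dtype=np.complex128)
        return cls(u=u0.astype(np.complex128), p=zeros2.copy(), y=zeros2.copy(),
                   z=zeros3.copy(), y_dual=zeros2.copy(), z_dual=zeros3.copy())


def update_y(state: ADMMState, params: SolverParams) -> np.ndarray:
    """Shrinkage update of the gradient splitting variable y."""
    arg = tgv.grad(state.u) - state.p + state.y_dual
    return tgv.shrink_vec(arg, 1.0 / params.mu2)


def update_z(state: ADMMState, params: SolverParams) -> np.ndarray:
    """Shrinkage update of the symmetrized-gradient splitting variable z."""
    arg = tgv.sym_grad(state.p) + state.z_dual
    return tgv.shrink_frob(arg, 1.0 / params.mu3)


def update_duals(state: ADMMState, params: SolverParams
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Dual ascent on both splitting constraints (returns new duals)."""
    y_dual = state.y_dual + params.mu * (tgv.grad(state.u) - state.p - state.y)
    z_dual = state.z_dual + params.mu * (tgv.sym_grad(state.p) - state.z)
    return y_dual, z_dual


# ---------------------------------------------------------------------------
# spectral (u, p) solve
# ---------------------------------------------------------------------------


def _difference_symbols(n: int) -> tuple[np.ndarray, np.ndarray]:
    """DFT symbols of the periodic forward differences D1 (axis 1), D2 (axis 0)."""
    w = np.exp(2j * np.pi * np.arange(n) / n) - 1.0
    d1 = np.broadcast_to(w[None, :], (n, n))
    d2 = np.broadcast_to(w[:, None], (n, n))
    return d1, d2


class SpectralSystem:
    """Per-frequency 3x3 normal-equation coefficients for the (u, p) solve.

    Blocks (Hermitian layout, unknowns ordered u, p1, p2):

        a11 = lambda0*M + a1m2 (|d1|^2 + |d2|^2) + beta * mask
        a22 = a1m2 + a0m3 (|d1|^2 + |d2|^2 / 2)
        a33 = a1m2 + a0m3 (|d2|^2 + |d1|^2 / 2)
        a12 = -a1m2 conj(d1)     a13 = -a1m2 conj(d2)
        a23 = (a0m3 / 2) conj(d2) d1

    with a1m2 = alpha1*mu2, a0m3 = alpha0*mu3 and d_j the forward-difference
    symbols; ``mask`` is the diagonal of P^T P in the unshifted DFT layout.
    Cached per (n, mask, weights).
    """

    def __init__(self, mask: SamplingMask, params: SolverParams, beta: float,
                 patch_len: int):
        n = mask.n
        if params.lambda0 == 0 and beta == 0:
            raise ValueError("beta and lambda0 cannot both be zero")
        d1, d2 = _difference_symbols(n)
        a1m2 = params.alpha1 * params.mu2
        a0m3 = params.alpha0 * params.mu3
        self.n, self.beta = n, beta
        self.a1m2, self.a0m3 = a1m2, a0m3
        self.lambda0, self.patch_len = params.lambda0, patch_len
        q1, q2 = np.abs(d1) ** 2, np.abs(d2) ** 2
        self.a11 = (params.lambda0 * patch_len + a1m2 * (q1 + q2)
                    + beta * mask.keep)
        self.a22 = a1m2 + a0m3 * (q1 + 0.5 * q2)
        self.a33 = a1m2 + a0m3 * (q2 + 0.5 * q1)
        self.a12 = -a1m2 * d1.conj()
        self.a13 = -a1m2 * d2.conj()
        self.a23 = 0.5 * a0m3 * d2.conj() * d1
        # 3x3 Hermitian determinant per frequency
        self.denom = (self.a11 * (self.a22 * self.a33 - np.abs(self.a23) ** 2)
                      - self.a12 * (self.a12.conj() * self.a33
                                    - self.a23 * self.a13.conj())
                      + self.a13 * (self.a12.conj() * self.a23.conj()
                                    - self.a22 * self.a13.conj()))
        self.denom = self.denom.real.astype(np.float64)  # Hermitian PSD system
        if a1m2 > 0 or a0m3 > 0:
            dmax = np.abs(self.denom).max()
            if (beta > 0 or params.lambda0 > 0) and \
                    np.any(np.abs(self.denom) < 1e-15 * dmax):
                raise ValueError("singular spectral system despite positive "
                                 "beta/lambda0 — inconsistent configuration")
        self._denom_safe = np.where(np.abs(self.denom) < 1e-300, 1e-300,
                                    self.denom)

    def solve(self, rhs_u: np.ndarray, rhs_p1: np.ndarray, rhs_p2: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        """Solve the block system for image-domain right-hand sides."""
        f = lambda v: np.fft.fft2(v, norm="ortho")
        finv = lambda v: np.fft.ifft2(v, norm="ortho")
        B1, B2, B3 = f(rhs_u), f(rhs_p1), f(rhs_p2)
        a11, a22, a33 = self.a11, self.a22, self.a33
        a12, a13, a23 = self.a12, self.a13, self.a23
        a21, a31, a32 = a12.conj(), a13.conj(), a23.conj()

        if self.a1m2 == 0 and self.a0m3 == 0:
            # p enters no term: solve the scalar u equation, p stays zero
            u = finv(B1 / a11)
            n = self.n
            return u, np.zeros((2, n, n), dtype=np.complex128)

        # Cramer's rule on the 3x3 per-frequency system
        den = self._denom_safe
        u_hat = (B1 * (a22 * a33 - a23 * a32)
                 - a12 * (B2 * a33 - a23 * B3)
                 + a13 * (B2 * a32 - a22 * B3)) / den
        p1_hat = (a11 * (B2 * a33 - a23 * B3)
                  - B1 * (a21 * a33 - a23 * a31)
                  + a13 * (a21 * B3 - B2 * a31)) / den
        p2_hat = (a11 * (a22 * B3 - B2 * a32)
                  - a12 * (a21 * B3 - B2 * a31)
                  + B1 * (a21 * a32 - a22 * a31)) / den

        if self.a1m2 == 0:
            # p is unconstrained at frequencies where its 2x2 block is
            # singular (the DC mode of eps): take the minimum-norm choice
            sing = np.abs(self.denom) < 1e-12 * max(np.abs(self.denom).max(),
                                                    1e-300)
            if np.any(sing):
                u_hat = np.where(sing, B1 / a11, u_hat)
                p1_hat = np.where(sing, 0.0, p1_hat)
                p2_hat = np.where(sing, 0.0, p2_hat)

        u = finv(u_hat)
        p = np.stack([finv(p1_hat), finv(p2_hat)])
        return u, p


def _up_rhs(state: ADMMState, b: KSpaceData, beta: float, params: SolverParams,
            cfg: PatchConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Image-domain right-hand sides of the (u, p) normal equations."""
    n = b.mask.n
    a1m2 = params.alpha1 * params.mu2
    a0m3 = params.alpha0 * params.mu3
    q = state.y - state.y_dual
    s = state.z - state.z_dual

    rhs_u = beta * sampling.adjoint_measure(b)
    if params.lambda0 > 0:
        if state.A is None or state.codes is None:
            raise ValueError("lambda0 > 0 requires a dictionary and codes")
        rhs_u = rhs_u + params.lambda0 * patches.aggregate_patches(
            state.A @ state.codes, n, cfg)
    if a1m2 > 0:
        rhs_u = rhs_u + a1m2 * (tgv._d1t(q[0]) + tgv._d2t(q[1]))
    rhs_p1 = -a1m2 * q[0] + a0m3 * (tgv._d1t(s[0]) + tgv._d2t(s[2]))
    rhs_p2 = -a1m2 * q[1] + a0m3 * (tgv._d2t(s[1]) + tgv._d1t(s[2]))
    return rhs_u, rhs_p1, rhs_p2


def solve_up(state: ADMMState, b: KSpaceData, params: SolverParams,
             cfg: PatchConfig, beta: float | None = None,
             system: SpectralSystem | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Exact minimizer of the quadratic (u, p) subproblem.

    Requires stride-1 wrap-around patches so that R^T R is patch_len times
    the identity and the whole system stays diagonal in the DFT basis.
    """
    if params.lambda0 > 0 and (cfg.stride != 1 or not cfg.wrap):
        raise ValueError("the closed-form solve needs stride=1 wrap-around "
                         "patches (R^T R proportional to identity)")
    if beta is None:
        beta = params.resolved_beta(b.sigma)
    if system is None:
        system = SpectralSystem(b.mask, params, beta, cfg.patch_len)
    rhs = _up_rhs(state, b, beta, params, cfg)
    return system.solve(*rhs)


def objective(state: ADMMState, b: KSpaceData, params: SolverParams,
              cfg: PatchConfig, beta: float | None = None) -> float:
    """Value of the full variational objective at the current state.

    The L1 code penalty is reported as zero: sparsity is enforced as a
    hard per-patch cap inside OMP rather than through a weight.
    """
    if beta is None:
        beta = params.resolved_beta(b.sigma)
    ku = sampling.forward_measure(state.u, b.mask).values
    val = 0.5 * beta * float(np.linalg.norm(ku - b.values) ** 2)
    if params.lambda0 > 0 and state.A is not None:
        fit = state.A @ state.codes - patches.extract_patches(state.u, cfg)
        val += 0.5 * params.lambda0 * float(np.linalg.norm(fit) ** 2)
    val += tgv.tgv2_penalty(state.u, state.p, params.alpha0, params.alpha1)
    return val


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class ReconstructionResults:
    """Estimates and diagnostics from a fitted :class:`ReconstructionModel`.

    Attributes
    ----------
    image : the reconstructed complex image u
    zero_filled : the zero-filled initialization K* b
    history : per-inner-iteration DataFrame (objective, data residual,
        primal residuals, PSNR when a reference is known)
    outer_objectives : objective value at the end of each outer iteration
    """

    def __init__(self, model: "ReconstructionModel", state: ADMMState,
                 history: pd.DataFrame, outer_objectives: list[float],
                 converged: bool):
        self.model = model
        self.state = state
        self.image = state.u
        self.zero_filled = model.zero_filled
        self.history = history
        self.outer_objectives = outer_objectives
        self.converged = converged

    @property
    def dictionary(self) -> np.ndarray | None:
        return self.state.A

    @property
    def n_iterations(self) -> int:
        return len(self.history)

    def psnr(self, reference: np.ndarray | None = None) -> float:
        ref = self.model.reference if reference is None else reference
        if ref is None:
            raise ValueError("no reference image available")
        return metrics.psnr(ref, self.image)

    def hfen(self, reference: np.ndarray | None = None) -> float:
        ref = self.model.reference if reference is None else reference
        if ref is None:
            raise ValueError("no reference image available")
        return metrics.hfen(ref, self.image)

    def summary(self) -> str:
        p = self.model.params
        mask = self.model.kspace.mask
        lines = [
            "Patch-dictionary + TGV reconstruction",
            "=" * 46,
            f"grid                 {mask.n} x {mask.n}",
            f"sampling scheme      {mask.scheme}",
            f"undersampling factor {sampling.undersampling_factor(mask):.2f}",
            f"noise sigma          {self.model.kspace.sigma:g}",
            f"beta (resolved)      {self.model.beta:g}",
            f"lambda0/alpha1/alpha0 {p.lambda0:g} / {p.alpha1:g} / {p.alpha0:g}",
            f"iterations run       {self.n_iterations}"
            f" ({'converged' if self.converged else 'max iters'})",
            f"final objective      {self.history['objective'].iloc[-1]:.6g}",
        ]
        if self.model.reference is not None:
            lines += [
                f"PSNR (zero-filled)   "
                f"{metrics.psnr(self.model.reference, self.zero_filled):.2f} dB",
                f"PSNR (reconstruction) {self.psnr():.2f} dB",
                f"HFEN (reconstruction) {self.hfen():.4f}",
            ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Objective and primal residual trajectories (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.semilogy(h["iteration"], h["objective"], label="objective")
        ax.semilogy(h["iteration"], h["primal_res_y"], label="||Du - p - y||")
        ax.semilogy(h["iteration"], h["primal_res_z"], label="||eps(p) - z||")
        ax.set_xlabel("inner iteration")
        ax.legend()
        return ax

    def plot_images(self, axes=None):
        """Magnitude of zero-filled vs reconstruction (and error if ref known)."""
        import matplotlib.pyplot as plt

        ref = self.model.reference
        ncols = 3 if ref is not None else 2
        if axes is None:
            _, axes = plt.subplots(1, ncols, figsize=(4 * ncols, 4))
        axes[0].imshow(np.abs(self.zero_filled), cmap="gray")
        axes[0].set_title("zero-filled")
        axes[1].imshow(np.abs(self.image), cmap="gray")
        axes[1].set_title("reconstruction")
        if ref is not None:
            axes[2].imshow(np.abs(np.abs(self.image) - np.abs(ref)), cmap="hot")
            axes[2].set_title("|error|")
        for ax in axes:
            ax.axis("off")
        return axes


class ReconstructionModel:
    """Undersampled-MRI reconstruction model for one k-space measurement.

    Parameters
    ----------
    kspace : the measured (possibly noisy) undersampled k-space data
    params : solver weights and iteration controls
    patch_config : patch geometry (stride-1 wrap-around by default)
    dl_params : dictionary-learning controls
    dict_size : number of atoms J (default 4x overcomplete)
    reference : optional ground-truth image for PSNR logging
    """

    def __init__(self, kspace: KSpaceData, params: SolverParams | None = None,
                 patch_config: PatchConfig | None = None,
                 dl_params: DLParams | None = None,
                 dict_size: int | None = None,
                 reference: np.ndarray | None = None):
        self.kspace = kspace
        self.params = params or SolverParams()
        self.patch_config = patch_config or PatchConfig()
        self.dl_params = dl_params or DLParams()
        M = self.patch_config.patch_len
        self.dict_size = dict_size or 4 * M
        self.reference = None if reference is None else np.asarray(reference)
        self.beta = self.params.resolved_beta(kspace.sigma)
        self.zero_filled = sampling.adjoint_measure(kspace)

    @classmethod
    def from_image(cls, image: np.ndarray, scheme: str = "radial",
                   factor: float = 4.0, sigma: float = 0.0, seed: int = 0,
                   **kwargs) -> "ReconstructionModel":
        """Simulate a measurement from a ground-truth image, keep it as ref."""
        image = np.asarray(image)
        mask = sampling.make_mask(scheme, image.shape[0], factor, seed)
        b = sampling.forward_measure(image, mask)
        b = sampling.add_noise(b, sigma, seed + 1)
        kwargs.setdefault("reference", image)
        return cls(b, **kwargs)

    def _coding_tolerance(self, outer: int) -> float:
        """Per-patch absolute coding budget for the given outer iteration.

        Continuation: start at the estimated aliasing level and decay
        geometrically, but never below the k-space noise propagated to the
        patch scale (1.15 x the per-pixel noise std, the usual
        dictionary-denoising margin).
        """
        params, b = self.params, self.kspace
        root_m = np.sqrt(self.patch_config.patch_len)
        err0 = params.code_err0
        if err0 is None:
            rms = np.sqrt(np.mean(np.abs(self.zero_filled) ** 2))
            err0 = 0.4 * rms * root_m
        sigma_img = b.sigma * np.sqrt(2.0 * b.values.size) / b.mask.n
        floor = 1.15 * sigma_img * root_m
        return max(err0 * params.code_err_decay ** outer, floor)

    def fit(self) -> ReconstructionResults:
        params, cfg, b = self.params, self.patch_config, self.kspace
        n = b.mask.n
        state = ADMMState.initial(self.zero_filled)
        system = SpectralSystem(b.mask, params, self.beta, cfg.patch_len)

        rows = []
        outer_objectives = []
        converged = False
        it = 0
        A = None
        for outer in range(params.outer_iters):
            if params.lambda0 > 0:
                X = patches.extract_patches(state.u, cfg)
                if A is None:  # warm-start across outer iterations
                    A = dictlearn.init_dictionary(cfg.patch_len, self.dict_size)
                dl = replace(self.dl_params,
                             omp_tol_abs=self._coding_tolerance(outer))
                A, codes = dictlearn.learn_codes_and_dictionary(X, A, dl)
                state.A, state.codes = A, codes
            u_prev_outer = state.u.copy()
            for _ in range(params.admm_iters):
                it += 1
                state.y = update_y(state, params)
                state.z = update_z(state, params)
                u_prev = state.u
                state.u, state.p = solve_up(state, b, params, cfg,
                                            beta=self.beta, system=system)
                state.y_dual, state.z_dual = update_duals(state, params)

                if not np.all(np.isfinite(state.u)):
                    raise FloatingPointError("non-finite image iterate")
                ku = sampling.forward_measure(state.u, b.mask).values
                row = {
                    "iteration": it,
                    "outer": outer + 1,
                    "objective": objective(state, b, params, cfg,
                                           beta=self.beta),
                    "data_residual": float(np.linalg.norm(ku - b.values)),
                    "primal_res_y": float(np.linalg.norm(
                        tgv.grad(state.u) - state.p - state.y)),
                    "primal_res_z": float(np.linalg.norm(
                        tgv.sym_grad(state.p) - state.z)),
                    "rel_change": float(np.linalg.norm(state.u - u_prev)
                                        / max(np.linalg.norm(u_prev), 1e-30)),
                }
                if self.reference is not None:
                    row["psnr"] = metrics.psnr(self.reference, state.u)
                rows.append(row)
            outer_objectives.append(rows[-1]["objective"])
            rel_outer = (np.linalg.norm(state.u - u_prev_outer)
                         / max(np.linalg.norm(u_prev_outer), 1e-30))
            if rel_outer < params.tol:
                converged = True
                break

        history = pd.DataFrame(rows)
        return ReconstructionResults(self, state, history, outer_objectives,
                                     converged)


def reconstruct(b: KSpaceData, params: SolverParams | None = None,
                patch_config: PatchConfig | None = None,
                dl_params: DLParams | None = None,
                reference: np.ndarray | None = None,
                **kwargs) -> ReconstructionResults:
    """One-call reconstruction: build the model and fit it."""
    model = ReconstructionModel(b, params=params, patch_config=patch_config,
                                dl_params=dl_params, reference=reference,
                                **kwargs)
    return model.fit()
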