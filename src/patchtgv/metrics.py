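"""Image-quality metrics and synthetic test images.

PSNR is computed on magnitude images with the reference's peak magnitude;
HFEN (high-frequency error norm) is the relative L2 norm of the
Laplacian-of-Gaussian filtered magnitude difference, the standard edge- and
fine-feature-sensitive companion metric for compressed-sensing MRI.  The
phantom generators stand in for scanner data: an analytic Shepp-Logan head
phantom on [0, 255] and a complex-valued variant with a smooth spatial
phase, emulating the phase roll of real MR acquisitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["psnr", "hfen", "log_kernel", "shepp_logan", "complex_phantom",
           "run_sweep"]


def psnr(ref: np.ndarray, rec: np.ndarray) -> float:
    """Peak signal-to-noise ratio, dB, on magnitude images.

    ``20 log10(peak / rmse)`` with peak the maximum magnitude of the
    reference.  Identical images return ``inf``.
    """
    ref = np.abs(np.asarray(ref))
    rec = np.abs(np.asarray(rec))
    if ref.shape != rec.shape:
        raise ValueError("images must share the same grid")
    peak = ref.max()
    if peak == 0:
        raise ValueError("all-zero reference: peak undefined")
    mse = np.mean((ref - rec) ** 2)
    if mse == 0:
        return float("inf")
    return float(20.0 * np.log10(peak / np.sqrt(mse)))


def log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Zero-sum Laplacian-of-Gaussian kernel (rotationally symmetric)."""
    half = (size - 1) / 2.0
    x, y = np.meshgrid(np.arange(size) - half, np.arange(size) - half)
    r2 = x ** 2 + y ** 2
    g = np.exp(-r2 / (2 * sigma ** 2))
    g /= g.sum()
    h = g * (r2 - 2 * sigma ** 2) / sigma ** 4
    return h - h.mean()


_LOG15 = log_kernel(15, 1.5)


def hfen(ref: np.ndarray, rec: np.ndarray) -> float:
    """High-frequency error norm (relative form).

    ``||LoG(|rec|) - LoG(|ref|)||_2 / ||LoG(|ref|)||_2`` with a 15x15
    Laplacian-of-Gaussian kernel (sigma 1.5) and symmetric boundaries.
    """
    ref = np.abs(np.asarray(ref)).astype(float)
    rec = np.abs(np.asarray(rec)).astype(float)
    if ref.shape != rec.shape:
        raise ValueError("images must share the same grid")
    lref = ndimage.convolve(ref, _LOG15, mode="reflect")
    lrec = ndimage.convolve(rec, _LOG15, mode="reflect")
    denom = np.linalg.norm(lref)
    if denom <= 1e-10 * max(np.linalg.norm(ref), 1.0):
        raise ValueError("flat reference: HFEN undefined")
    return float(np.linalg.norm(lrec - lref) / denom)


# modified Shepp-Logan ellipses: (intensity, a, b, x0, y0, angle_deg)
_SHEPP_LOGAN_ELLIPSES = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


def shepp_logan(n: int) -> np.ndarray:
    """Modified Shepp-Logan head phantom on an n-by-n grid, range [0, 255].

    Analytic superposition of the standard 10 ellipses; deterministic, any
    resolution.  Returned as a complex image with zero imaginary part.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    axis = (np.arange(n) - (n - 1) / 2) / ((n - 1) / 2)
    x, y = np.meshgrid(axis, -axis)  # y up, matching the tomography convention
    img = np.zeros((n, n))
    for amp, a, b, x0, y0, ang in _SHEPP_LOGAN_ELLIPSES:
        th = np.deg2rad(ang)
        xr = (x - x0) * np.cos(th) + (y - y0) * np.sin(th)
        yr = -(x - x0) * np.sin(th) + (y - y0) * np.cos(th)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    img = np.clip(img, 0.0, None)
    return (255.0 * img).astype(np.complex128)


def complex_phantom(n: int, phase_scale: float = 1.0, seed: int = 0) -> np.ndarray:
    """Complex-valued phantom: Shepp-Logan magnitude times a smooth phase.

    The phase is a random low-order (quadratic) polynomial field scaled by
    ``phase_scale`` radians; the magnitude equals ``shepp_logan(n)``
    exactly, whatever the phase.
    """
    mag = np.abs(shepp_logan(n))
    rng = np.random.default_rng(seed)
    c = rng.normal(size=6)
    axis = np.linspace(-1, 1, n)
    x, y = np.meshgrid(axis, axis)
    poly = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x ** 2 + c[5] * y ** 2
    phase = phase_scale * poly / max(np.abs(poly).max(), 1e-30)
    return mag * np.exp(1j * phase)


def run_sweep(schemes, factors, sigmas, params=None, n: int = 128,
              seed: int = 0, image: np.ndarray | None = None,
              **recon_kwargs) -> pd.DataFrame:
    """Reconstruct the phantom over a grid of (scheme, factor, sigma).

    Returns one row per condition with achieved factor, PSNR of the
    zero-filled baseline and of the reconstruction, and HFEN.  Deterministic
    given ``seed``.
    """
    from . import sampling
    from .solver import ReconstructionModel

    ref = shepp_logan(n) if image is None else np.asarray(image)
    rows = []
    for scheme in schemes:
        for factor in factors:
            mask = sampling.make_mask(scheme, ref.shape[0], factor, seed)
            clean = sampling.forward_measure(ref, mask)
            for sigma in sigmas:
                b = sampling.add_noise(clean, sigma, seed + 1)
                model = ReconstructionModel(b, params=params, reference=ref,
                                            **recon_kwargs)
                res = model.fit()
                rows.append({
                    "scheme": scheme,
                    "factor": factor,
                    "achieved_factor": sampling.undersampling_factor(mask),
                    "sigma": sigma,
                    "psnr_zero_filled": psnr(ref, model.zero_filled),
                    "psnr": res.psnr(),
                    "hfen": res.hfen(),
                    "iterations": res.n_iterations,
                })
    return pd.DataFrame(rows)
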