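"""Undersampled Fourier measurement model and k-space sampling masks.

The acquisition operator is ``K = P F`` where ``F`` is the *unitary* 2D DFT
(DC stored at array index ``(0, 0)``) and ``P`` selects the sampled k-space
locations.  Measurements are ``b = K u + xi`` with complex white Gaussian
noise ``xi``.  The unitary convention makes ``K* K`` an orthogonal projector
in the image domain, which the spectral solver in :mod:`patchtgv.solver`
relies on.

Masks are stored in the same unshifted layout as the DFT output; generators
work in centred (fftshifted) coordinates internally and always keep the DC
location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "forward_measure",
    "adjoint_measure",
    "add_noise",
    "make_mask",
    "undersampling_factor",
    "SCHEMES",
]

SCHEMES = ("radial", "random2d", "cartesian1d", "spiral", "full")


def _as_image(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u)
    if u.ndim != 2 or u.shape[0] != u.shape[1]:
        raise ValueError(f"image must be square 2D, got shape {u.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("image contains non-finite values")
    return u.astype(np.complex128, copy=False)


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space selection pattern on the n-by-n DFT grid.

    ``keep`` uses the unshifted DFT layout (DC at index ``(0, 0)``).
    """

    keep: np.ndarray
    scheme: str = "full"
    seed: int | None = None

    def __post_init__(self):
        keep = np.asarray(self.keep, dtype=bool)
        if keep.ndim != 2 or keep.shape[0] != keep.shape[1]:
            raise ValueError("mask must be square 2D")
        if not keep.any():
            raise ValueError("mask keeps no k-space location")
        object.__setattr__(self, "keep", keep)

    @property
    def n(self) -> int:
        return self.keep.shape[0]

    @property
    def num_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class KSpaceData:
    """Vector of sampled k-space values plus the mask that produced it."""

    values: np.ndarray
    mask: SamplingMask
    sigma: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 1 or self.values.size != self.mask.num_kept:
            raise ValueError(
                f"expected {self.mask.num_kept} k-space values, got {self.values.shape}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def forward_measure(u: np.ndarray, mask: SamplingMask) -> KSpaceData:
    """Apply ``K = P F``: unitary 2D DFT restricted to the kept locations."""
    u = _as_image(u)
    if u.shape[0] != mask.n:
        raise ValueError(f"image side {u.shape[0]} != mask side {mask.n}")
    spectrum = np.fft.fft2(u, norm="ortho")
    return KSpaceData(values=spectrum[mask.keep], mask=mask)


def adjoint_measure(b: KSpaceData) -> np.ndarray:
    """Apply ``K*``: insert values at kept locations, inverse unitary DFT.

    With no further processing this is the zero-filled reconstruction used
    to initialise the solver.
    """
    spectrum = np.zeros((b.mask.n, b.mask.n), dtype=np.complex128)
    spectrum[b.mask.keep] = b.values
    return np.fft.ifft2(spectrum, norm="ortho")


def add_noise(b: KSpaceData, sigma: float, seed: int) -> KSpaceData:
    """Add complex white Gaussian noise (std ``sigma`` per real/imag channel)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return KSpaceData(values=b.values.copy(), mask=b.mask, sigma=0.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=(2, b.values.size))
    values = b.values + noise[0] + 1j * noise[1]
    return KSpaceData(values=values, mask=b.mask, sigma=float(sigma))


def undersampling_factor(mask: SamplingMask) -> float:
    """Total grid locations divided by sampled locations (>= 1)."""
    return mask.n ** 2 / mask.num_kept


# ---------------------------------------------------------------------------
# mask generators (centred coordinates, then ifftshift to storage layout)
# ---------------------------------------------------------------------------


def _radial_keep(n: int, num_lines: int) -> np.ndarray:
    """Rasterize equiangular straight lines through the grid centre."""
    keep = np.zeros((n, n), dtype=bool)
    c = n // 2
    t = np.arange(-n, n, 0.5)
    for i in range(num_lines):
        theta = np.pi * i / num_lines
        rows = np.rint(c + t * np.sin(theta)).astype(int)
        cols = np.rint(c + t * np.cos(theta)).astype(int)
        ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
        keep[rows[ok], cols[ok]] = True
    return keep


def _spiral_keep(n: int, pitch: float) -> np.ndarray:
    """Rasterize a single-shot Archimedean spiral r = pitch * theta."""
    keep = np.zeros((n, n), dtype=bool)
    c = n // 2
    r_max = n / np.sqrt(2.0)
    theta = 0.0
    while True:
        r = pitch * theta
        if r > r_max:
            break
        row = int(round(c + r * np.sin(theta)))
        col = int(round(c + r * np.cos(theta)))
        if 0 <= row < n and 0 <= col < n:
            keep[row, col] = True
        theta += 0.5 / max(r, 1.0)
    keep[c, c] = True
    return keep


def _search_count(build, lo: float, hi: float, target: int, steps: int = 40,
                  increasing: bool = True):
    """Bisect a scalar knob so the kept count of ``build(knob)`` nears target."""
    best = None
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        keep = build(mid)
        cnt = int(keep.sum())
        if best is None or abs(cnt - target) < best[0]:
            best = (abs(cnt - target), keep)
        more = cnt < target
        if more == increasing:
            lo = mid
        else:
            hi = mid
    return best[1]


def make_mask(scheme: str, n: int, target_factor: float = 1.0,
              seed: int = 0) -> SamplingMask:
    """Generate a sampling mask of the given scheme.

    Parameters
    ----------
    scheme : {"radial", "random2d", "cartesian1d", "spiral", "full"}
    n : grid side length (>= 8)
    target_factor : desired undersampling factor n^2 / kept
    seed : RNG seed for the randomized schemes

    The achieved factor is within 15% of the target for reachable targets;
    the DC location is always kept.
    """
    if n < 8:
        raise ValueError("n must be at least 8")
    if target_factor < 1:
        raise ValueError("target_factor must be >= 1")
    if target_factor > n * n:
        raise ValueError("target_factor exceeds the number of grid locations")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")

    c = n // 2
    target_kept = max(1, round(n * n / target_factor))

    if scheme == "full":
        keep = np.ones((n, n), dtype=bool)

    elif scheme == "radial":
        # kept count grows with the number of lines; search over integers
        lo, hi = 1, 4 * n
        best = None
        while lo <= hi:
            mid = (lo + hi) // 2
            cnt = int(_radial_keep(n, mid).sum())
            if best is None or abs(cnt - target_kept) < best[0]:
                best = (abs(cnt - target_kept), mid)
            if cnt < target_kept:
                lo = mid + 1
            else:
                hi = mid - 1
        keep = _radial_keep(n, best[1])

    elif scheme == "spiral":
        # smaller pitch -> denser spiral -> more cells kept
        keep = _search_count(lambda a: _spiral_keep(n, a), 1e-3, float(n),
                             target_kept, increasing=False)

    elif scheme == "cartesian1d":
        rng = np.random.default_rng(seed)
        n_rows = max(1, round(n / target_factor))
        band = max(1, min(n_rows, round(0.04 * n)))
        half = band // 2
        central = np.arange(c - half, c - half + band)
        others = np.setdiff1d(np.arange(n), central)
        extra = rng.choice(others, size=n_rows - band, replace=False)
        keep = np.zeros((n, n), dtype=bool)
        keep[np.concatenate([central, extra]), :] = True

    elif scheme == "random2d":
        rng = np.random.default_rng(seed)
        ii, jj = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        r = np.hypot(ii, jj)
        r0 = max(1.5, n / 32)
        keep = np.zeros((n, n), dtype=bool)
        keep[r <= r0] = True  # fully kept central disk
        need = target_kept - int(keep.sum())
        if need > 0:
            outside = np.flatnonzero(~keep.ravel())
            w = 1.0 / (1.0 + (r.ravel()[outside] / r0) ** 2)
            picked = rng.choice(outside, size=min(need, outside.size),
                                replace=False, p=w / w.sum())
            keep.ravel()[picked] = True

    keep[c, c] = True  # DC in centred coordinates
    mask = SamplingMask(keep=np.fft.ifftshift(keep), scheme=scheme, seed=seed)

    achieved = undersampling_factor(mask)
    if scheme != "full" and not (0.85 * target_factor <= achieved <= 1.15 * target_factor):
        raise ValueError(
            f"{scheme} mask reached factor {achieved:.2f}, "
            f"outside 15% of target {target_factor:.2f}"
        )
    return mask
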