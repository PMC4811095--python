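"""Patch extraction operator R and its transpose.

``extract_patches`` maps an n-by-n image to the matrix ``Ru`` whose columns
are vectorized b-by-b blocks, one per patch origin; ``aggregate_patches`` is
the exact adjoint ``R^T``.  With stride 1 and periodic wrap-around every
pixel lies in exactly ``M = b^2`` patches, so ``R^T R = M * I`` — the scalar
identity the image update in :mod:`patchtgv.solver` depends on to stay
diagonal in the DFT basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchConfig", "extract_patches", "aggregate_patches", "patch_grid_shape"]


@dataclass(frozen=True)
class PatchConfig:
    """Geometry of the patch decomposition.

    side : patch side length b in pixels
    stride : spacing between patch origins
    wrap : periodic wrap-around at image borders
    """

    side: int = 6
    stride: int = 1
    wrap: bool = True

    def __post_init__(self):
        if self.side < 1 or self.stride < 1:
            raise ValueError("side and stride must be positive")
        if self.stride > self.side:
            raise ValueError("stride larger than patch side leaves gaps")

    @property
    def patch_len(self) -> int:
        """Number of pixels per patch, M = side^2."""
        return self.side * self.side


def patch_grid_shape(n: int, cfg: PatchConfig) -> tuple[int, int]:
    """Number of patch origins along each axis."""
    if cfg.side > n:
        raise ValueError(f"patch side {cfg.side} exceeds image side {n}")
    if cfg.wrap:
        per_axis = len(range(0, n, cfg.stride))
        return per_axis, per_axis
    per_axis = len(range(0, n - cfg.side + 1, cfg.stride))
    return per_axis, per_axis


def _origin_indices(n: int, cfg: PatchConfig) -> np.ndarray:
    if cfg.wrap:
        return np.arange(0, n, cfg.stride)
    return np.arange(0, n - cfg.side + 1, cfg.stride)


def _index_grids(n: int, cfg: PatchConfig) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) pixel index arrays of shape (G, G, b, b)."""
    origins = _origin_indices(n, cfg)
    offs = np.arange(cfg.side)
    idx = origins[:, None] + offs[None, :]  # (G, b)
    if cfg.wrap:
        idx = idx % n
    rows = idx[:, None, :, None]
    cols = idx[None, :, None, :]
    return np.broadcast_to(rows, (idx.shape[0],) * 2 + (cfg.side,) * 2), \
        np.broadcast_to(cols, (idx.shape[0],) * 2 + (cfg.side,) * 2)


def extract_patches(u: np.ndarray, cfg: PatchConfig) -> np.ndarray:
    """Return the patch matrix ``Ru`` of shape (M, I).

    Column k holds the vectorized b-by-b block at the k-th origin; origins
    and within-patch pixels are both ordered row-major.
    """
    u = np.asarray(u)
    n = u.shape[0]
    if u.ndim != 2 or u.shape[1] != n:
        raise ValueError("image must be square 2D")
    if cfg.side > n:
        raise ValueError(f"patch side {cfg.side} exceeds image side {n}")
    rows, cols = _index_grids(n, cfg)
    pat = u[rows, cols]  # (G, G, b, b)
    g = pat.shape[0] * pat.shape[1]
    return pat.reshape(g, cfg.patch_len).T


def aggregate_patches(pm: np.ndarray, n: int, cfg: PatchConfig) -> np.ndarray:
    """Adjoint of :func:`extract_patches`: add each patch into its origin.

    Satisfies ``<Ru, Y> = <u, aggregate(Y)>`` for all u and Y.
    """
    pm = np.asarray(pm)
    gr, gc = patch_grid_shape(n, cfg)
    if pm.shape != (cfg.patch_len, gr * gc):
        raise ValueError(
            f"patch matrix shape {pm.shape} inconsistent with n={n}, cfg={cfg}"
        )
    rows, cols = _index_grids(n, cfg)
    out = np.zeros((n, n), dtype=np.result_type(pm.dtype, np.float64))
    blocks = pm.T.reshape(gr, gc, cfg.side, cfg.side)
    np.add.at(out, (rows, cols), blocks)
    return out
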