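"""Discrete second-order TGV calculus.

Second-order total generalized variation of an image u is

    TGV_a^2(u) = min_p  a1 * ||Du - p||_1  +  a0 * ||eps(p)||_1

where ``D`` is the forward-difference gradient with periodic boundaries,
``p = (p1, p2)`` is an auxiliary vector field and ``eps(p)`` the symmetrized
gradient, per pixel the symmetric 2x2 matrix

    [[ D1 p1,              (D2 p1 + D1 p2)/2 ],
     [ (D2 p1 + D1 p2)/2,  D2 p2            ]].

Both L1 norms are isotropic (Euclidean over the 2-vector, Frobenius over the
2x2 matrix), matching the shrinkage operators that solve their proximal
subproblems.  The regularizer favours piecewise-affine images: where p can
follow the local gradient, only the second-derivative term pays, which
avoids the staircase artifacts of plain TV.

Conventions: vector fields are arrays of shape ``(2, n, n)``; symmetric
tensor fields are ``(3, n, n)`` storing ``(z1, z2, z3)`` with z3 the single
off-diagonal entry.  The tensor inner product counts z3 twice, so
``sym_div`` is the exact (negative) adjoint of ``sym_grad`` under it and
``shrink_frob`` is the exact proximal map of the Frobenius L1 term.
Axis 1 of the image is "x" (operator D1), axis 0 is "y" (operator D2).
All operators accept complex fields; shrinkage then acts on moduli and
rescales the complex components.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "grad", "div", "sym_grad", "sym_div",
    "shrink_vec", "shrink_frob", "tgv2_penalty",
]


def _d1(u):
    """Forward difference along axis 1 (x), periodic."""
    return np.roll(u, -1, axis=-1) - u


def _d2(u):
    """Forward difference along axis 0 (y), periodic."""
    return np.roll(u, -1, axis=-2) - u


def _d1t(u):
    """Adjoint of ``_d1``."""
    return np.roll(u, 1, axis=-1) - u


def _d2t(u):
    """Adjoint of ``_d2``."""
    return np.roll(u, 1, axis=-2) - u


def grad(u: np.ndarray) -> np.ndarray:
    """Forward-difference gradient ``Du = (D1 u, D2 u)``, shape (2, n, n)."""
    return np.stack([_d1(u), _d2(u)])


def div(p: np.ndarray) -> np.ndarray:
    """Divergence, the negative adjoint of :func:`grad`.

    ``<grad(u), p> = -<u, div(p)>`` for all u, p.
    """
    return -(_d1t(p[0]) + _d2t(p[1]))


def sym_grad(p: np.ndarray) -> np.ndarray:
    """Symmetrized gradient eps(p), shape (3, n, n) as (z1, z2, z3)."""
    return np.stack([_d1(p[0]), _d2(p[1]), 0.5 * (_d2(p[0]) + _d1(p[1]))])


def sym_div(z: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`sym_grad` under the weighted inner product.

    With ``<z, w> = sum(z1 w1* + z2 w2* + 2 z3 w3*)``,
    ``<sym_grad(p), z> = -<p, sym_div(z)>``.
    """
    return -np.stack([_d1t(z[0]) + _d2t(z[2]), _d2t(z[1]) + _d1t(z[2])])


def _scale_by_shrunk_norm(a: np.ndarray, norm: np.ndarray, thr: float) -> np.ndarray:
    shrunk = np.maximum(norm - thr, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(norm > 0, shrunk / np.where(norm > 0, norm, 1.0), 0.0)
    return a * scale


def shrink_vec(a: np.ndarray, thr: float) -> np.ndarray:
    """Isotropic soft-threshold of a pixel-wise 2-vector field.

    Proximal map of ``thr * ||.||_2`` applied per pixel: zero when the
    Euclidean magnitude is at or below ``thr``, otherwise the magnitude
    shrinks by ``thr`` with the direction (and complex phase) preserved.
    """
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    norm = np.sqrt(np.abs(a[0]) ** 2 + np.abs(a[1]) ** 2)
    return _scale_by_shrunk_norm(a, norm, thr)


def shrink_frob(z: np.ndarray, thr: float) -> np.ndarray:
    """Frobenius soft-threshold of a pixel-wise symmetric 2x2 field.

    The Frobenius magnitude counts the stored off-diagonal entry twice:
    ``|B|_F^2 = |z1|^2 + |z2|^2 + 2 |z3|^2``.
    """
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    norm = np.sqrt(np.abs(z[0]) ** 2 + np.abs(z[1]) ** 2 + 2 * np.abs(z[2]) ** 2)
    return _scale_by_shrunk_norm(z, norm, thr)


def tgv2_penalty(u: np.ndarray, p: np.ndarray, alpha0: float, alpha1: float) -> float:
    """Evaluate ``a1 ||Du - p||_1 + a0 ||eps(p)||_1`` (isotropic norms)."""
    d = grad(u) - p
    e = sym_grad(p)
    term1 = np.sqrt(np.abs(d[0]) ** 2 + np.abs(d[1]) ** 2).sum()
    term0 = np.sqrt(np.abs(e[0]) ** 2 + np.abs(e[1]) ** 2 + 2 * np.abs(e[2]) ** 2).sum()
    return float(alpha1 * term1 + alpha0 * term0)
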