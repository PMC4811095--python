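"""Adaptive patch-dictionary learning: OMP sparse coding + K-SVD updates.

Given a patch matrix X (columns = vectorized patches) the pair (A, Gamma)
approximately solving

    min_{A, Gamma} ||A Gamma - X||_F^2   s.t.  ||Gamma_i||_0 <= tau per column

is found by alternating orthogonal matching pursuit (codes with A fixed) and
K-SVD (one rank-1 SVD per atom, jointly refitting the atom and its nonzero
code row).  Everything is done natively over the complex field: OMP uses
conjugate (Hermitian) inner products and K-SVD a complex rank-1 factor, so
complex-valued MR images never need real/imaginary splitting.

The alternation keeps the Frobenius fit non-increasing: the K-SVD sweep is
monotone atom by atom, and the coding step keeps the previous code for any
column where the fresh greedy OMP solution would fit worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DLParams",
    "init_dictionary",
    "omp_encode",
    "ksvd_update",
    "learn_codes_and_dictionary",
]


@dataclass
class DLParams:
    """Dictionary-learning knobs.

    sparsity : max nonzero coefficients per patch (OMP stopping cap)
    ksvd_iters : number of code/dictionary alternations per call
    omp_tol_rel : OMP also stops once the residual drops below
        ``omp_tol_rel * ||patch||``
    omp_tol_abs : absolute residual stopping threshold (intensity units,
        per patch vector); 0 disables it.  The reconstruction solver drives
        this to make the coding discard aliasing/noise instead of fitting it.
    seed : RNG seed (only randomized choices: none at present; kept for
        forward compatibility of the alternation)
    """

    sparsity: int = 7
    ksvd_iters: int = 5
    omp_tol_rel: float = 1e-6
    omp_tol_abs: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sparsity < 1:
            raise ValueError("sparsity must be >= 1")
        if self.ksvd_iters < 1:
            raise ValueError("ksvd_iters must be >= 1")


def _check_dictionary(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=np.complex128)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms < 1e-12):
        raise ValueError("dictionary contains a (near) zero atom")
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("dictionary atoms must have unit norm")
    return A


def init_dictionary(M: int, J: int) -> np.ndarray:
    """Overcomplete 2D-DCT dictionary of J unit-norm atoms of length M.

    Built as the Kronecker product of two 1D overcomplete DCT frames on a
    b-by-b patch (b = sqrt(M)).  When J is not a perfect square the smallest
    sufficient Kronecker frame is built and its first J columns are kept.
    The first atom is the constant (flat) atom, which absorbs patch means.
    Deterministic.
    """
    if J < M:
        raise ValueError("dictionary must be at least complete (J >= M)")
    b = int(round(np.sqrt(M)))
    if b * b != M:
        raise ValueError("patch length M must be a perfect square")
    k1 = int(np.ceil(np.sqrt(J)))
    k1 = max(k1, b)
    i = np.arange(b)[:, None]
    k = np.arange(k1)[None, :]
    frame = np.cos(np.pi * k * (2 * i + 1) / (2 * k1))
    frame /= np.linalg.norm(frame, axis=0)
    full = np.kron(frame, frame)[:, :J]
    full /= np.linalg.norm(full, axis=0)
    return full.astype(np.complex128)


def omp_encode(X: np.ndarray, A: np.ndarray, params: DLParams) -> np.ndarray:
    """Sparse-code every column of X in dictionary A by batch OMP.

    Greedy per column: pick the atom with the largest conjugate correlation
    ``|a_k^H r|`` with the current residual, re-solve least squares on the
    active set, stop after ``sparsity`` atoms or when the residual norm
    falls below ``omp_tol_rel * ||x||``.  Returns the dense (J, I) code
    matrix Gamma.
    """
    A = _check_dictionary(A)
    X = np.asarray(X, dtype=np.complex128)
    M, J = A.shape
    if X.shape[0] != M:
        raise ValueError(f"patch length {X.shape[0]} != atom length {M}")
    I = X.shape[1]
    tau = min(params.sparsity, J)

    gram = A.conj().T @ A                     # (J, J)
    corr0 = A.conj().T @ X                    # (J, I)
    norm2 = np.einsum("mi,mi->i", X.conj(), X).real
    tol2 = np.maximum((params.omp_tol_rel ** 2) * norm2,
                      params.omp_tol_abs ** 2)

    support = np.zeros((I, tau), dtype=np.intp)
    coef = np.zeros((I, tau), dtype=np.complex128)
    active = norm2 > tol2                     # columns still being coded
    nsel = np.zeros(I, dtype=np.intp)
    residual = X.copy()

    for t in range(tau):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        corr = A.conj().T @ residual[:, idx]  # (J, Iact)
        # never reselect an atom already in the support
        for s in range(t):
            corr[support[idx, s], np.arange(idx.size)] = 0.0
        pick = np.argmax(np.abs(corr), axis=0)
        support[idx, t] = pick
        nsel[idx] = t + 1

        S = support[idx, : t + 1]                        # (Iact, t+1)
        G = gram[S[:, :, None], S[:, None, :]]           # (Iact, t+1, t+1)
        rhs = corr0[S, idx[:, None]]                     # (Iact, t+1)
        G = G + 1e-13 * np.eye(t + 1)                    # guard near-duplicates
        sol = np.linalg.solve(G, rhs[..., None])[..., 0]
        coef[idx, : t + 1] = sol

        # exact-LS residual: r = x - A_S c, and ||r||^2 = ||x||^2 - Re(c^H rhs)
        atoms = A[:, S.reshape(-1)].reshape(M, idx.size, t + 1)
        residual[:, idx] = X[:, idx] - (atoms * sol[None, :, :]).sum(-1)
        res2 = norm2[idx] - np.einsum("it,it->i", sol.conj(), rhs).real
        done = res2 <= np.maximum(tol2[idx], 0.0)
        active[idx[done]] = False

    codes = np.zeros((J, I), dtype=np.complex128)
    used = np.arange(tau)[None, :] < nsel[:, None]     # (I, tau), row-major
    codes[support[used], np.repeat(np.arange(I), nsel)] = coef[used]
    return codes


def ksvd_update(A: np.ndarray, codes: np.ndarray, X: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """One K-SVD sweep: refit every atom (and its code row) by rank-1 SVD.

    For atom k with support S (patches using it), the restricted residual
    ``E = X_S - A Gamma_S + a_k Gamma_{k,S}`` is factored by its leading
    singular pair; the atom becomes the left singular vector and the code
    row the conjugated right singular vector scaled by the singular value
    (computed from the M-by-M Hermitian ``E E^H``, which is the exact
    rank-1 truncation).  Atoms used by no patch are replaced by the
    currently worst-represented patch, normalized.  The Frobenius fit never
    increases.  Returns the updated (A, codes); inputs are not modified.
    """
    A = _check_dictionary(A).copy()
    codes = np.asarray(codes, dtype=np.complex128).copy()
    X = np.asarray(X, dtype=np.complex128)
    M, J = A.shape
    residual = X - A @ codes

    for k in range(J):
        row = codes[k]
        S = np.flatnonzero(row)
        if S.size == 0:
            worst = int(np.argmax(np.einsum("mi,mi->i", residual.conj(),
                                            residual).real))
            cand = X[:, worst]
            nrm = np.linalg.norm(cand)
            if nrm > 1e-12:
                A[:, k] = cand / nrm
            continue
        E = residual[:, S] + np.outer(A[:, k], row[S])
        C = E @ E.conj().T                    # (M, M) Hermitian
        w, V = np.linalg.eigh(C)
        if w[-1] <= 1e-24:
            continue  # degenerate residual: keep the previous atom
        atom = V[:, -1]
        # deterministic phase: largest-magnitude entry made real positive
        j = int(np.argmax(np.abs(atom)))
        atom = atom * np.exp(-1j * np.angle(atom[j]))
        new_row = atom.conj() @ E             # sigma * v^H, shape (|S|,)
        residual[:, S] = E - np.outer(atom, new_row)
        A[:, k] = atom
        codes[k, S] = new_row
    return A, codes


def _column_errors(X: np.ndarray, A: np.ndarray, codes: np.ndarray) -> np.ndarray:
    R = X - A @ codes
    return np.einsum("mi,mi->i", R.conj(), R).real


def _cleanup(A: np.ndarray, codes: np.ndarray, X: np.ndarray,
             coherence_thresh: float = 0.99, usage_thresh: int = 4) -> None:
    """Replace degenerate atoms by the worst-represented patches, in place.

    An atom is degenerate when it nearly duplicates another atom (mutual
    coherence above ``coherence_thresh``) or codes almost no patches.  The
    replacement perturbs the alternation out of the local minima where two
    ground-truth features share one atom; the best-iterate tracking in
    :func:`learn_codes_and_dictionary` absorbs the transient error bump.
    """
    col_err = _column_errors(X, A, codes)
    usage = (np.abs(codes) > 1e-10).sum(axis=1)
    coh = np.abs(A.conj().T @ A)
    np.fill_diagonal(coh, 0.0)
    for k in range(A.shape[1]):
        if coh[k].max() > coherence_thresh or usage[k] < usage_thresh:
            worst = int(np.argmax(col_err))
            nrm = np.linalg.norm(X[:, worst])
            if nrm < 1e-12:
                continue
            A[:, k] = X[:, worst] / nrm
            codes[k, :] = 0.0
            col_err[worst] = 0.0
            coh = np.abs(A.conj().T @ A)
            np.fill_diagonal(coh, 0.0)


def learn_codes_and_dictionary(X: np.ndarray, A0: np.ndarray, params: DLParams,
                               return_errors: bool = False):
    """Alternate OMP coding and K-SVD sweeps for ``params.ksvd_iters`` rounds.

    Greedy OMP re-coding can occasionally fit worse than the previous round,
    so the pair actually returned — and the error trajectory reported — is
    the best iterate seen so far; the trajectory is therefore
    non-increasing.  Between rounds, near-duplicate and almost-unused atoms
    are replaced by the worst-represented patches (the usual K-SVD
    dictionary cleanup).

    Returns the best (A, Gamma), plus the per-alternation error trajectory
    when ``return_errors`` is set.
    """
    A = _check_dictionary(A0).copy()
    X = np.asarray(X, dtype=np.complex128)
    best: tuple[np.ndarray, np.ndarray] | None = None
    best_err = np.inf
    errors = []
    for it in range(params.ksvd_iters):
        codes = omp_encode(X, A, params)
        A, codes = ksvd_update(A, codes, X)
        err = float(np.linalg.norm(X - A @ codes, "fro"))
        if err < best_err:
            best_err = err
            best = (A.copy(), codes.copy())
        errors.append(best_err)
        if it + 1 < params.ksvd_iters:
            _cleanup(A, codes, X)
    A, codes = best
    if return_errors:
        return A, codes, errors
    return A, codes
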