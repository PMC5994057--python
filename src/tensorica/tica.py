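"""Tensorial ICA: FOBI and JADE rotations on tPCA-whitened tensors.

The tICA model writes the data tensor as ``X = S (x)_1 O1 (x)_2 O2`` with the
source slices ``S[k1, k2, :]`` mutually statistically independent, zero-mean
and unit-variance across features.  Whitening (tPCA projection plus variance
scaling) reduces the problem to finding one orthogonal rotation per mode;
the rotations are estimated from fourth-order statistics:

* FOBI eigendecomposes a matricised quartic moment matrix
  ``B_m = mean_i[M_i M_i^T M_i M_i^T]`` built from the per-realisation
  mode-``m`` flattenings ``M_i`` — the natural tensor generalisation of the
  classical fourth-order blind identification matrix ``E[||x||^2 x x^T]``,
  to which it reduces exactly when the other mode has size 1.
* JADE jointly diagonalises the classical fourth-cumulant matrices computed
  on the pooled mode-``m`` fibers, via Givens (Jacobi) sweeps.

Composing whitening with the rotations gives the tWFOBI and tWJADE
estimators.  Non-Gaussian sources are identifiable; components are ranked
by excess kurtosis, which is large for the sparse, heavy-tailed sources of
variation typical of omic data and zero for Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import TPCAModel, whiten
from .tensor_core import OmicsTensor, mode_multiply

__all__ = [
    "TICAModel",
    "fobi_rotation",
    "jade_rotation",
    "joint_diagonalize",
    "twfobi",
    "twjade",
    "excess_kurtosis",
    "rank_components",
    "project_mode1",
]


def excess_kurtosis(v: np.ndarray) -> float:
    """Excess kurtosis ``m4/m2**2 - 3`` from central moments.

    Zero for Gaussian data, positive for heavy-tailed/sparse sources.  No
    small-sample bias correction is applied.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 4:
        raise ValueError(f"kurtosis requires at least 4 observations, got {v.size}")
    c = v - v.mean()
    m2 = np.mean(c**2)
    if m2 <= 0:
        raise ValueError("kurtosis undefined for zero-variance data")
    return float(np.mean(c**4) / m2**2 - 3.0)


def _fix_column_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return V


def _mode_slices(X: OmicsTensor, m: int) -> np.ndarray:
    """(p, d_m, d_other) array of per-realisation mode-m flattenings."""
    slices = np.moveaxis(X.values, 2, 0)
    if m == 2:
        slices = np.swapaxes(slices, 1, 2)
    return slices


def fobi_rotation(Xw: OmicsTensor, m: int) -> np.ndarray:
    """FOBI rotation for mode ``m`` of a whitened tensor.

    Eigendecomposes ``B_m = (1/p) sum_i M_i M_i^T M_i M_i^T`` (``M_i`` the
    mode-``m`` flattening of realisation ``i``) and returns the orthogonal
    eigenvector matrix, eigenvalue-descending, each column's
    largest-magnitude entry positive.  Deterministic.
    """
    if m not in (1, 2):
        raise ValueError(f"mode must be 1 or 2, got {m}")
    Ms = _mode_slices(Xw, m)  # (p, d_m, d_other)
    MMt = np.einsum("iab,icb->iac", Ms, Ms)
    B = np.einsum("iab,ibc->ac", MMt, MMt) / Ms.shape[0]
    lam, U = np.linalg.eigh(0.5 * (B + B.T))
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    gaps = np.abs(np.diff(lam))
    scale = max(np.abs(lam).max(), 1.0)
    if lam.size > 1 and np.any(gaps < 1e-10 * scale):
        warnings.warn(
            "FOBI quartic-moment matrix has (near-)tied eigenvalues; the "
            "rotation is not identifiable within the tied subspace",
            stacklevel=2,
        )
    return _fix_column_signs(U)


def _pooled_fibers(Xw: OmicsTensor, m: int) -> np.ndarray:
    """All mode-m fibers, stacked as an (N, d_m) array with N = p * d_other."""
    Ms = _mode_slices(Xw, m)  # (p, d_m, d_other)
    return np.swapaxes(Ms, 1, 2).reshape(-1, Ms.shape[1])


def _cumulant_matrices(R: np.ndarray) -> list[np.ndarray]:
    """Symmetrised fourth-cumulant matrices of whitened vectors.

    ``C[ij] = mean_n[r_i r_j r r^T] - delta_ij I - e_i e_j^T - e_j e_i^T``
    for all i <= j; all ``d(d+1)/2`` matrices are returned (no eigen-matrix
    truncation).
    """
    N, d = R.shape
    eye = np.eye(d)
    mats = []
    for i in range(d):
        for j in range(i, d):
            w = R[:, i] * R[:, j]
            C = (R.T * w) @ R / N
            if i == j:
                C = C - eye - 2.0 * np.outer(eye[i], eye[i])
            else:
                C = C - np.outer(eye[i], eye[j]) - np.outer(eye[j], eye[i])
            mats.append(0.5 * (C + C.T))
    return mats


def joint_diagonalize(
    mats: list[np.ndarray], tol: float = 1e-8, max_sweeps: int = 100
) -> np.ndarray:
    """Joint approximate diagonalisation by Givens (Jacobi) rotations.

    Sweeps over index pairs, solving each 2x2 subproblem in closed form
    (the principal eigenvector of the accumulated Jacobi matrix gives the
    optimal angle); stops when every rotation angle in a sweep is below
    ``tol`` or after ``max_sweeps``.  The summed squared off-diagonal mass
    is non-increasing across sweeps.
    """
    A = np.array([np.asarray(M, dtype=float) for M in mats])
    if A.ndim != 3 or A.shape[1] != A.shape[2]:
        raise ValueError("joint_diagonalize expects square matrices of equal size")
    asym = max(
        (np.abs(M - M.T).max() for M in A), default=0.0
    )
    if asym > 1e-8:
        raise ValueError(f"input matrices are not symmetric (max asymmetry {asym:.3g})")
    d = A.shape[1]
    V = np.eye(d)
    if d == 1:
        return V
    for _ in range(max_sweeps):
        max_angle = 0.0
        for p in range(d - 1):
            for q in range(p + 1, d):
                # closed-form optimal Givens angle for the pair (p, q)
                h1 = A[:, p, p] - A[:, q, q]
                h2 = A[:, p, q] + A[:, q, p]
                G = np.array(
                    [[h1 @ h1, h1 @ h2], [h1 @ h2, h2 @ h2]]
                )
                evals, evecs = np.linalg.eigh(G)
                x, y = evecs[:, np.argmax(evals)]
                if x < 0:
                    x, y = -x, -y
                r = np.hypot(x, y)
                if r == 0:
                    continue
                c = np.sqrt((x + r) / (2.0 * r))
                s = y / np.sqrt(2.0 * r * (x + r))
                if abs(s) <= tol:
                    continue
                max_angle = max(max_angle, abs(s))
                # rotate all matrices and accumulate V
                rot_p = c * A[:, :, p] + s * A[:, :, q]
                rot_q = -s * A[:, :, p] + c * A[:, :, q]
                A[:, :, p], A[:, :, q] = rot_p, rot_q
                rot_p = c * A[:, p, :] + s * A[:, q, :]
                rot_q = -s * A[:, p, :] + c * A[:, q, :]
                A[:, p, :], A[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if max_angle <= tol:
            break
    return V


def jade_rotation(Xw: OmicsTensor, m: int) -> np.ndarray:
    """JADE rotation for mode ``m`` of a whitened tensor.

    Builds the ``d(d+1)/2`` symmetrised fourth-cumulant matrices over the
    pooled mode-``m`` fibers and jointly diagonalises them.  Columns of the
    returned orthogonal matrix are ordered by decreasing excess kurtosis of
    the corresponding rotated fiber components, sign-fixed.
    """
    if m not in (1, 2):
        raise ValueError(f"mode must be 1 or 2, got {m}")
    R = _pooled_fibers(Xw, m)
    N, d = R.shape
    if d == 1:
        return np.eye(1)
    if N < d * d:
        warnings.warn(
            f"only {N} pooled fibers for a {d}-dimensional rotation "
            f"(< d^2 = {d * d}); cumulant estimates may be unstable",
            stacklevel=2,
        )
    V = joint_diagonalize(_cumulant_matrices(R))
    proj = R @ V
    kurt = [excess_kurtosis(proj[:, j]) for j in range(d)]
    order = np.argsort(-np.asarray(kurt), kind="stable")
    return _fix_column_signs(V[:, order])


@dataclass
class TICAModel:
    """A fitted tensorial ICA decomposition.

    Attributes
    ----------
    unmixing
        Per-mode ``d_m x p_m`` matrices ``W_m`` (rotation composed with
        whitening); ``source = centered X (x)_1 W_1 (x)_2 W_2``.
    mixing
        Per-mode ``p_m x d_m`` pseudo-inverses ``A_m`` of ``W_m``.
    source
        Source tensor of shape ``(d1, d2, p)``.
    offsets
        ``p1 x p2`` centering offsets removed before unmixing.
    kurtosis
        ``d1 x d2`` excess kurtoses of the source slices.
    order
        Permutation of mode-2 components by decreasing max-over-mode-1
        excess kurtosis (stable under ties).
    """

    unmixing: tuple[np.ndarray, np.ndarray]
    mixing: tuple[np.ndarray, np.ndarray]
    source: OmicsTensor
    offsets: np.ndarray
    kurtosis: np.ndarray
    order: np.ndarray
    whitening: TPCAModel
    method: str

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.source.shape


def _slice_sign(v: np.ndarray) -> float:
    """+1/-1 so that the slice has non-negative skewness; fallback on the
    largest-|weight| entry when skewness is numerically zero."""
    sk = stats.skew(v)
    if abs(sk) >= 1e-8:
        return 1.0 if sk >= 0 else -1.0
    k = np.argmax(np.abs(v))
    return 1.0 if v[k] >= 0 else -1.0


def _fix_component_signs(
    S: np.ndarray, W1: np.ndarray, W2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve per-mode sign indeterminacy.

    Only one sign per mode-1 and per mode-2 component is free, so slice
    skewness is pooled over the other mode: mode-1 signs first, then mode-2,
    each chosen to make the pooled skewness of the affected slices
    non-negative.
    """
    d1, d2, _ = S.shape
    for k in range(d1):
        s = _slice_sign(S[k].ravel())
        S[k] *= s
        W1[k] *= s
    for j in range(d2):
        s = _slice_sign(S[:, j].ravel())
        S[:, j] *= s
        W2[j] *= s
    return S, W1, W2


def _tica_fit(
    X: OmicsTensor,
    dims,
    rotation,
    method: str,
    center: bool = True,
) -> TICAModel:
    Xw, wmodel = whiten(X, dims=dims, scale=True, center=center)
    U1 = rotation(Xw, 1)
    U2 = rotation(Xw, 2)
    S = mode_multiply(mode_multiply(Xw, U1.T, 1), U2.T, 2)
    b1, b2 = wmodel.bases
    W1 = U1.T @ (b1.omega_reduced / np.sqrt(b1.lam_reduced)).T
    W2 = U2.T @ (b2.omega_reduced / np.sqrt(b2.lam_reduced)).T
    Sv, W1, W2 = _fix_component_signs(S.values.copy(), W1, W2)
    S = S.with_values(Sv)
    A1 = np.linalg.pinv(W1)
    A2 = np.linalg.pinv(W2)
    d1, d2, _ = S.shape
    kurt = np.array(
        [[excess_kurtosis(Sv[k, j]) for j in range(d2)] for k in range(d1)]
    )
    order = np.argsort(-kurt.max(axis=0), kind="stable")
    return TICAModel(
        unmixing=(W1, W2),
        mixing=(A1, A2),
        source=S,
        offsets=wmodel.offsets,
        kurtosis=kurt,
        order=order,
        whitening=wmodel,
        method=method,
    )


def twfobi(X: OmicsTensor, dims="rmt", center: bool = True) -> TICAModel:
    """Whitened tensorial FOBI: tPCA whitening followed by per-mode FOBI
    rotations.  Deterministic given the input."""
    return _tica_fit(X, dims, fobi_rotation, "twfobi", center=center)


def twjade(X: OmicsTensor, dims="rmt", center: bool = True) -> TICAModel:
    """Whitened tensorial JADE: tPCA whitening followed by per-mode joint
    diagonalisation of fourth-cumulant matrices.  Deterministic given the
    input."""
    return _tica_fit(X, dims, jade_rotation, "twjade", center=center)


def rank_components(model: TICAModel) -> pd.DataFrame:
    """Per-(data-type, component) kurtosis table, mode-2 components ordered
    by decreasing max-over-mode-1 excess kurtosis (stable index tie-break)."""
    d1, d2, _ = model.shape
    rows = []
    for rank, j in enumerate(model.order, start=1):
        for k in range(d1):
            rows.append(
                {
                    "rank": rank,
                    "component": int(j),
                    "mode1_index": k,
                    "mode1_label": model.source.mode1_labels[k]
                    if k < len(model.source.mode1_labels)
                    else f"c{k + 1}",
                    "kurtosis": model.kurtosis[k, j],
                    "max_kurtosis": model.kurtosis[:, j].max(),
                }
            )
    return pd.DataFrame(rows)


def project_mode1(model: TICAModel) -> OmicsTensor:
    """Rotate the source tensor back onto the original mode-1 (data-type)
    axes: ``source (x)_1 A_1``.

    Gives per-data-type weight vectors for each mode-2 component, the form
    in which components are interpreted (feature selection, enrichment,
    cell-type specificity).  Requires mode 1 unreduced (``d1 = p1``).
    """
    A1 = model.mixing[0]
    if A1.shape[0] != A1.shape[1]:
        raise ValueError(
            "mode-1 back-projection requires an unreduced mode 1 "
            f"(d1={A1.shape[1]} < p1={A1.shape[0]})"
        )
    out = mode_multiply(model.source, A1, 1)
    return out.with_values(out.values, mode1_labels=list(model.source.mode1_labels))
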