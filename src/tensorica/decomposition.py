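"""Tensorial PCA, random-matrix dimension estimation and tPCA whitening.

Tensorial PCA decomposes an order-3 tensor ``X`` as ``X = S (x)_1 O1 (x)_2 O2``
where each ``O_m`` is the orthogonal eigenvector matrix of the mode-m
covariance of the centered tensor.  The ranked eigenvalues support
dimensional reduction: the number of components carrying real signal in a
data matrix is estimated by counting eigenvalues of its sample correlation
matrix above the Marchenko-Pastur upper edge, the largest eigenvalue
expected under pure noise.

Whitening composes the reduced tPCA projection with per-mode eigenvalue
rescaling so that retained components have unit variance — the standard
preprocessing for the ICA rotations in :mod:`tensorica.tica`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tensor_core import OmicsTensor, center_realisations, mode_covariance, mode_multiply

__all__ = [
    "ModeBasis",
    "TPCAModel",
    "tpca_fit",
    "rmt_estimate_dim",
    "whiten",
    "whiten_mode",
    "resolve_dims",
]

# Eigenvalues below this fraction of the largest are treated as exactly zero.
_DEGENERATE_RTOL = 1e-12


class DegenerateWhiteningError(ValueError):
    """Raised when a retained eigenvalue is (numerically) zero."""


@dataclass
class ModeBasis:
    """Orthogonal eigenbasis of one mode covariance.

    Attributes
    ----------
    omega
        ``p_m x p_m`` orthogonal matrix; columns are eigenvectors in
        eigenvalue-descending order, each column's largest-magnitude entry
        made positive.
    lam
        Eigenvalues, sorted non-increasing, clipped at zero.
    d
        Retained dimension, ``1 <= d <= p_m``.
    """

    omega: np.ndarray
    lam: np.ndarray
    d: int

    @property
    def omega_reduced(self) -> np.ndarray:
        return self.omega[:, : self.d]

    @property
    def lam_reduced(self) -> np.ndarray:
        return self.lam[: self.d]


@dataclass
class TPCAModel:
    """Fitted tensorial PCA: per-mode bases, centering offsets and source.

    ``source`` has shape ``(d1, d2, p)``; at full dimensions,
    ``source (x)_1 O1 (x)_2 O2 + offsets`` reconstructs the input.
    """

    bases: tuple[ModeBasis, ModeBasis]
    offsets: np.ndarray
    source: OmicsTensor

    def reconstruct(self) -> OmicsTensor:
        Y = mode_multiply(self.source, self.bases[0].omega_reduced, 1)
        Y = mode_multiply(Y, self.bases[1].omega_reduced, 2)
        return Y.with_values(Y.values + self.offsets[:, :, None])


def _eig_descending(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalue-descending, sign-fixed."""
    lam, vec = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    # deterministic sign: largest-|entry| of each column made positive
    for j in range(vec.shape[1]):
        k = np.argmax(np.abs(vec[:, j]))
        if vec[k, j] < 0:
            vec[:, j] = -vec[:, j]
    return np.clip(lam, 0.0, None), vec


def rmt_estimate_dim(M: np.ndarray) -> int:
    """Estimate the number of signal components in a data matrix.

    ``M`` is ``n_obs x n_var`` (observations in rows).  Columns are
    standardised and the eigenvalues of their sample correlation matrix are
    compared with the Marchenko-Pastur upper edge ``(1 + sqrt(n_var/n_obs))**2``:
    under pure i.i.d. noise no eigenvalue is expected above it, so the count
    of exceedances estimates the signal dimension.  Deterministic for fixed
    input.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("rmt_estimate_dim requires an n_obs x n_var matrix, both >= 2")
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all columns have zero variance")
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance column(s) from the "
            "RMT estimate",
            stacklevel=2,
        )
        M = M[:, keep]
        sd = sd[keep]
    n_obs, n_var = M.shape
    Z = (M - M.mean(axis=0)) / sd
    corr = (Z.T @ Z) / n_obs
    lam = np.linalg.eigvalsh(corr)
    edge = (1.0 + np.sqrt(n_var / n_obs)) ** 2
    return int(np.sum(lam > edge))


def resolve_dims(
    X: OmicsTensor, dims: str | tuple[int, int] | list[int] = "rmt"
) -> tuple[int, int]:
    """Resolve a dims policy to concrete retained dimensions ``(d1, d2)``.

    ``"full"`` keeps every component.  ``"rmt"`` keeps mode 1 (data type)
    full — it is small in every intended application — and sets the mode-2
    (sample) dimension to the maximum of the per-type RMT estimates computed
    on each type's feature x sample matrix, floored at 1.
    """
    p1, p2, p = X.shape
    if dims == "full":
        return p1, p2
    if dims == "rmt":
        if p2 <= 3:
            return p1, p2  # no reduction for small dimensions
        d2 = max(rmt_estimate_dim(X.values[k].T) for k in range(p1))
        return p1, min(max(d2, 1), p2)
    d1, d2 = int(dims[0]), int(dims[1])
    if not (1 <= d1 <= p1 and 1 <= d2 <= p2):
        raise ValueError(f"requested dims {(d1, d2)} exceed tensor modes {(p1, p2)}")
    return d1, d2


def tpca_fit(
    X: OmicsTensor,
    dims: str | tuple[int, int] = "full",
    center: bool = True,
) -> TPCAModel:
    """Fit tensorial PCA.

    Each mode covariance of the centered tensor is eigendecomposed
    (``C_m = O_m diag(lam_m) O_m^T``) and the source is the centered tensor
    contracted with the retained transposed bases.  With full dimensions the
    decomposition is an exact orthogonal change of basis.
    """
    p1, p2, p = X.shape
    if p <= max(p1, p2):
        warnings.warn(
            f"feature count p={p} does not exceed max(p1, p2)={max(p1, p2)}; "
            "mode covariances may be rank-deficient",
            stacklevel=2,
        )
    d1, d2 = resolve_dims(X, dims)
    if center:
        Xc, offsets = center_realisations(X)
    else:
        Xc, offsets = X, np.zeros((p1, p2))
    bases = []
    for m, d in ((1, d1), (2, d2)):
        lam, omega = _eig_descending(mode_covariance(Xc, m, normalize=True))
        bases.append(ModeBasis(omega=omega, lam=lam, d=d))
    S = mode_multiply(Xc, bases[0].omega_reduced.T, 1)
    S = mode_multiply(S, bases[1].omega_reduced.T, 2)
    return TPCAModel(bases=(bases[0], bases[1]), offsets=offsets, source=S)


def whiten_mode(
    X: OmicsTensor, m: int, d: int | None = None, scale: bool = True
) -> tuple[OmicsTensor, ModeBasis]:
    """Whiten a single mode of an (already centered) tensor.

    Projects mode ``m`` onto its top ``d`` covariance eigenvectors and, with
    ``scale``, divides by the square-rooted eigenvalues so the output's
    mode-``m`` covariance is the identity exactly.
    """
    lam, omega = _eig_descending(mode_covariance(X, m, normalize=True))
    p_m = X.shape[m - 1]
    d = p_m if d is None else d
    if not 1 <= d <= p_m:
        raise ValueError(f"retained dimension {d} out of range for mode {m}")
    basis = ModeBasis(omega=omega, lam=lam, d=d)
    lam_r = basis.lam_reduced
    if scale:
        if np.any(lam_r <= _DEGENERATE_RTOL * max(lam[0], np.finfo(float).tiny)):
            raise DegenerateWhiteningError(
                f"mode {m}: a retained eigenvalue is numerically zero; "
                "reduce the retained dimension"
            )
        W = basis.omega_reduced.T / np.sqrt(lam_r)[:, None]
    else:
        W = basis.omega_reduced.T
    return mode_multiply(X, W, m), basis


def whiten(
    X: OmicsTensor,
    dims: str | tuple[int, int] = "rmt",
    scale: bool = True,
    center: bool = True,
) -> tuple[OmicsTensor, TPCAModel]:
    """tPCA whitening of both decomposed modes.

    The tensor is centered, then modes 1 and 2 are whitened sequentially
    (mode 1 first, each from the covariance of the current tensor).  The
    mode whitened last has exactly identity covariance; joint whiteness of
    both modes holds approximately and improves with the feature count.

    Returns the whitened tensor together with a :class:`TPCAModel` whose
    bases carry the eigenvectors/eigenvalues used per mode (mode-2
    eigenvalues are those of the mode-1-whitened tensor).
    """
    p1, p2, _ = X.shape
    d1, d2 = resolve_dims(X, dims)
    if center:
        Xc, offsets = center_realisations(X)
    else:
        Xc, offsets = X, np.zeros((p1, p2))
    Xw, basis1 = whiten_mode(Xc, 1, d1, scale=scale)
    Xw, basis2 = whiten_mode(Xw, 2, d2, scale=scale)
    model = TPCAModel(bases=(basis1, basis2), offsets=offsets, source=Xw)
    return Xw, model
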