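"""Order-3 tensor algebra for multi-omic data.

A multi-omic experiment measuring ``p1`` data (or tissue) types on ``p2``
samples over ``p`` features is arranged as an order-3 tensor of shape
``(p1, p2, p)``.  The feature axis (mode 3) is treated as the axis of
independent, identically distributed realisations of a ``p1 x p2`` random
matrix; all decompositions act on modes 1 and 2 only.

This module provides the primitive operations the decompositions are built
from: per-(type, sample) centering across features, mode contraction
(multiplying a tensor by a matrix along one mode), mode covariance (the
``p_m x p_m`` matrix of summed outer products over all other indices), and
realisation-wise matricisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OmicsTensor",
    "center_realisations",
    "mode_multiply",
    "mode_covariance",
    "mode_flatten",
    "mode_stack",
]


class InvalidInputError(ValueError):
    """Raised on non-finite or otherwise unusable numeric input."""


class ShapeError(ValueError):
    """Raised on dimension mismatches between tensors and matrices."""


@dataclass
class OmicsTensor:
    """An order-3 data tensor (data-type x sample x feature) with axis labels.

    Parameters
    ----------
    values
        Real array of shape ``(p1, p2, p)``.  Mode 1 indexes the data or
        tissue type, mode 2 the sample, and mode 3 the feature.  Features
        are the i.i.d.-realisation axis.
    mode1_labels, mode2_labels, feature_ids
        Axis labels; generated automatically when omitted.
    """

    values: np.ndarray
    mode1_labels: list[str] = field(default=None)  # type: ignore[assignment]
    mode2_labels: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError(
                f"expected an order-3 array, got ndim={self.values.ndim}"
            )
        p1, p2, p = self.values.shape
        if p1 < 1 or p2 < 1 or p < 2:
            raise ShapeError(
                f"tensor shape {self.values.shape} violates p1>=1, p2>=1, p>=2"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("tensor contains non-finite values")
        if self.mode1_labels is None:
            self.mode1_labels = [f"type{i + 1}" for i in range(p1)]
        if self.mode2_labels is None:
            self.mode2_labels = [f"sample{i + 1}" for i in range(p2)]
        if self.feature_ids is None:
            self.feature_ids = [f"feature{i + 1}" for i in range(p)]
        for labels, n, name in (
            (self.mode1_labels, p1, "mode1_labels"),
            (self.mode2_labels, p2, "mode2_labels"),
            (self.feature_ids, p, "feature_ids"),
        ):
            if len(labels) != n:
                raise ShapeError(f"{name} has length {len(labels)}, expected {n}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **label_overrides) -> "OmicsTensor":
        """Return a new tensor with replaced values, inheriting labels."""
        labels = dict(
            mode1_labels=list(self.mode1_labels),
            mode2_labels=list(self.mode2_labels),
            feature_ids=list(self.feature_ids),
        )
        labels.update(label_overrides)
        return OmicsTensor(values, **labels)


def center_realisations(X: OmicsTensor) -> tuple[OmicsTensor, np.ndarray]:
    """Center each (type, sample) variable across its feature realisations.

    Returns the centered tensor together with the ``p1 x p2`` matrix of
    subtracted means; adding the offsets back reconstructs the input exactly.
    No variance scaling is applied at this stage.
    """
    offsets = X.values.mean(axis=2)
    centered = X.values - offsets[:, :, None]
    return X.with_values(centered), offsets


def mode_multiply(Z: OmicsTensor, A: np.ndarray, m: int) -> OmicsTensor:
    """Contract a tensor with a matrix along mode ``m`` (1 or 2).

    For a ``q x p_m`` matrix ``A``, the result has mode ``m`` of size ``q``
    with entries ``(Z (x)_m A)[..., i_m, ...] = sum_j Z[..., j, ...] A[i_m, j]``.
    """
    if m not in (1, 2):
        raise ValueError(f"mode must be 1 or 2, got {m}")
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ShapeError("contraction matrix must be 2-D")
    axis = m - 1
    if A.shape[1] != Z.values.shape[axis]:
        raise ShapeError(
            f"matrix has {A.shape[1]} columns but mode {m} has size "
            f"{Z.values.shape[axis]}"
        )
    out = np.moveaxis(np.tensordot(A, Z.values, axes=([1], [axis])), 0, axis)
    overrides = {}
    if A.shape[0] != A.shape[1]:
        key = "mode1_labels" if m == 1 else "mode2_labels"
        overrides[key] = [f"c{i + 1}" for i in range(A.shape[0])]
    return Z.with_values(out, **overrides)


def mode_covariance(X: OmicsTensor, m: int, normalize: bool = True) -> np.ndarray:
    """The ``p_m x p_m`` mode covariance: summed outer products over all
    other indices.

    With ``normalize`` the sum is divided by the number of summed terms
    (``p * p_other``) so eigenvalues are variance-scaled; the eigenvectors,
    and hence every rotation derived from them, do not depend on this choice.

    The input is expected to be centered; a warning (not an error) is issued
    when any per-(type, sample) mean across features exceeds ``1e-8``.
    """
    if m not in (1, 2):
        raise ValueError(f"mode must be 1 or 2, got {m}")
    means = np.abs(X.values.mean(axis=2))
    if means.max() > 1e-8:
        warnings.warn(
            "mode_covariance called on an uncentered tensor "
            f"(max per-slice mean {means.max():.3g})",
            stacklevel=2,
        )
    if m == 1:
        C = np.einsum("uji,vji->uv", X.values, X.values)
    else:
        C = np.einsum("jui,jvi->uv", X.values, X.values)
    C = 0.5 * (C + C.T)
    if normalize:
        p_other = X.values.shape[2 - m]  # the other decomposed mode
        C = C / (X.values.shape[2] * p_other)
    return C


def mode_flatten(X: OmicsTensor, m: int) -> list[np.ndarray]:
    """Matricise realisation-wise: one ``p_m x p_other`` matrix per feature.

    Element ``i`` is the ``p1 x p2`` slice of realisation ``i`` (transposed
    when ``m == 2``); :func:`mode_stack` is the exact inverse.
    """
    if m not in (1, 2):
        raise ValueError(f"mode must be 1 or 2, got {m}")
    slices = np.moveaxis(X.values, 2, 0)  # (p, p1, p2)
    if m == 2:
        slices = np.swapaxes(slices, 1, 2)
    return [slices[i].copy() for i in range(slices.shape[0])]


def mode_stack(
    matrices: list[np.ndarray], m: int, template: OmicsTensor | None = None
) -> OmicsTensor:
    """Re-stack the output of :func:`mode_flatten` into a tensor (bit-exact
    round trip)."""
    arr = np.stack(matrices, axis=0)
    if m == 2:
        arr = np.swapaxes(arr, 1, 2)
    values = np.moveaxis(arr, 0, 2)
    if template is not None:
        return template.with_values(values)
    return OmicsTensor(values)
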