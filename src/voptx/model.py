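"""Core algebra on excitation vectors and Hermitian 10 g-averaged SAR matrices.

In a parallel-transmit (pTx) MRI system the RF power deposited in tissue
depends on the complex per-channel drive.  For every voxel ``v`` a Hermitian,
positive-semidefinite matrix :math:`S_v` (the "Q-matrix", units W/kg per unit
input power) turns an excitation vector :math:`b \\in \\mathbb{C}^{N_{ch}}`
into the 10 g-averaged local SAR at that voxel via the quadratic form
:math:`b' S_v b`.  Everything else in this package — overestimation terms,
greedy VOP compression, safety evaluation — is built from the handful of
exact operations defined here: quadratic forms, set-wide maxima, the
worst-case SAR (largest eigenvalue over the set) and the arithmetic cost of
one VOP evaluation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

__all__ = [
    "ShapeError",
    "EmptySetError",
    "ValidationError",
    "SARMatrixSet",
    "power",
    "quadratic_form",
    "quadratic_forms",
    "hermitian_coeff_matrix",
    "hermitian_feature_matrix",
    "max_sar_over_set",
    "worst_case_sar",
    "op_count",
]

#: relative tolerance for the Hermitian check S == S'
HERMITIAN_RTOL = 1e-10
#: smallest eigenvalue must be >= -PSD_RTOL * largest eigenvalue
PSD_RTOL = 1e-10


class ShapeError(ValueError):
    """Dimension mismatch between an excitation vector and a SAR matrix."""


class EmptySetError(ValueError):
    """An operation that needs at least one SAR matrix received none."""


class ValidationError(ValueError):
    """A SAR matrix violates the Hermitian / PSD contract."""


def _hermitize(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + np.conjugate(np.swapaxes(m, -1, -2)))


def _check_hermitian(stack: np.ndarray, what: str, rtol: float = HERMITIAN_RTOL) -> None:
    asym = np.abs(stack - np.conjugate(np.swapaxes(stack, -1, -2)))
    scale = np.abs(stack).max(axis=(-1, -2), initial=0.0)
    worst = asym.max(axis=(-1, -2))
    bad = worst > rtol * np.maximum(scale, np.finfo(float).tiny)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValidationError(
            f"{what}: matrix {idx} is not Hermitian "
            f"(max asymmetry {worst.flat[idx]:.3e}, scale {scale.flat[idx]:.3e})"
        )


def _check_psd(stack: np.ndarray, what: str, rtol: float = PSD_RTOL) -> None:
    ev = np.linalg.eigvalsh(stack)
    lo, hi = ev[..., 0], ev[..., -1]
    bad = lo < -rtol * np.maximum(hi, np.finfo(float).tiny)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValidationError(
            f"{what}: matrix {idx} is not PSD "
            f"(lambda_min {lo.flat[idx]:.3e}, lambda_max {hi.flat[idx]:.3e})"
        )


@dataclasses.dataclass
class SARMatrixSet:
    """The uncompressed collection ``V_all`` of 10 g-averaged SAR matrices.

    Parameters
    ----------
    matrices
        Complex array of shape ``(n_voxels, n_channels, n_channels)``.
    voxel_ids
        Integer identifiers, one per matrix; defaults to ``arange``.
        Must be unique.
    global_matrix
        Optional Hermitian PSD matrix ``S_Global`` mapping an excitation
        vector to whole-body (global) SAR.
    metadata
        Free-form provenance dictionary.
    validate
        When true (default) every matrix is checked Hermitian and PSD.
    symmetrize
        Replace each matrix by ``(S + S')/2`` before validation, warning if
        the asymmetry exceeds the Hermitian tolerance.  File round-trip noise
        must not break downstream PSD logic.
    """

    matrices: np.ndarray
    voxel_ids: np.ndarray | None = None
    global_matrix: np.ndarray | None = None
    metadata: dict = dataclasses.field(default_factory=dict)
    validate: dataclasses.InitVar[bool] = True
    symmetrize: dataclasses.InitVar[bool] = False

    def __post_init__(self, validate: bool, symmetrize: bool) -> None:
        m = np.asarray(self.matrices, dtype=np.complex128)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ShapeError(
                f"matrices must have shape (n_voxels, n, n); got {m.shape}"
            )
        if m.shape[0] == 0:
            raise EmptySetError("a SARMatrixSet needs at least one matrix")
        if symmetrize:
            asym = np.abs(m - np.conjugate(np.swapaxes(m, -1, -2))).max()
            scale = max(float(np.abs(m).max()), np.finfo(float).tiny)
            if asym > HERMITIAN_RTOL * scale:
                warnings.warn(
                    f"symmetrizing SAR matrices: max asymmetry {asym:.3e} "
                    f"exceeds tolerance relative to scale {scale:.3e}",
                    stacklevel=2,
                )
            m = _hermitize(m)
        self.matrices = m
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(m.shape[0], dtype=np.int64)
        else:
            self.voxel_ids = np.asarray(self.voxel_ids, dtype=np.int64)
            if self.voxel_ids.shape != (m.shape[0],):
                raise ShapeError("voxel_ids length must match the matrix count")
            if np.unique(self.voxel_ids).size != self.voxel_ids.size:
                raise ValidationError("voxel_ids must be unique")
        if self.global_matrix is not None:
            g = np.asarray(self.global_matrix, dtype=np.complex128)
            if g.shape != (self.n_channels, self.n_channels):
                raise ShapeError(
                    f"global_matrix shape {g.shape} does not match "
                    f"n_channels={self.n_channels}"
                )
            if symmetrize:
                g = _hermitize(g)
            self.global_matrix = g
        self._lambda_max: np.ndarray | None = None
        if validate:
            _check_hermitian(self.matrices, "SARMatrixSet")
            _check_psd(self.matrices, "SARMatrixSet")
            if self.global_matrix is not None:
                _check_hermitian(self.global_matrix[None], "global_matrix")
                _check_psd(self.global_matrix[None], "global_matrix")

    # -- basic views -----------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def __len__(self) -> int:
        return self.n_voxels

    def lambda_max(self) -> np.ndarray:
        """Largest eigenvalue of every matrix (cached)."""
        if self._lambda_max is None:
            self._lambda_max = np.linalg.eigvalsh(self.matrices)[:, -1]
        return self._lambda_max

    def subset(self, positions: Sequence[int] | np.ndarray) -> "SARMatrixSet":
        """A new set holding the matrices at the given positions."""
        pos = np.asarray(positions, dtype=np.intp)
        return SARMatrixSet(
            self.matrices[pos],
            voxel_ids=self.voxel_ids[pos],
            global_matrix=self.global_matrix,
            metadata=dict(self.metadata),
            validate=False,
        )


# ---------------------------------------------------------------------------
# quadratic-form algebra
# ---------------------------------------------------------------------------

def power(b: np.ndarray) -> float:
    """Squared 2-norm of an excitation vector ("unit power" means 1)."""
    b = np.asarray(b, dtype=np.complex128).ravel()
    return float(np.real(np.vdot(b, b)))


def quadratic_form(b: np.ndarray, S: np.ndarray) -> float:
    """SAR value ``Re(b' S b)`` for one excitation vector and one matrix.

    For Hermitian ``S`` the form is real; the imaginary residue is asserted
    below ``1e-9`` of the result's magnitude before being discarded.
    """
    b = np.asarray(b, dtype=np.complex128).ravel()
    S = np.asarray(S, dtype=np.complex128)
    if S.shape != (b.size, b.size):
        raise ShapeError(
            f"vector of length {b.size} does not match matrix of shape {S.shape}"
        )
    val = complex(np.vdot(b, S @ b))
    if abs(val.imag) > 1e-9 * (abs(val.real) + 1e-12):
        raise ValidationError(
            f"quadratic form has imaginary residue {val.imag:.3e} "
            f"(matrix not Hermitian?)"
        )
    return val.real


def quadratic_forms(stack: np.ndarray, b: np.ndarray) -> np.ndarray:
    """``Re(b' S_v b)`` for one vector against a whole matrix stack."""
    b = np.asarray(b, dtype=np.complex128).ravel()
    stack = np.asarray(stack, dtype=np.complex128)
    if stack.shape[-1] != b.size:
        raise ShapeError(
            f"vector of length {b.size} does not match stack of shape {stack.shape}"
        )
    return np.einsum("i,...ij,j->...", b.conj(), stack, b).real


def hermitian_coeff_matrix(stack: np.ndarray) -> np.ndarray:
    """Pack Hermitian matrices into real coefficient rows of length n^2.

    For Hermitian ``S`` the quadratic form is real and bilinear in the real
    features of ``b``:  ``b'Sb = sum_i S_ii |b_i|^2 + 2 sum_{i<j} [Re S_ij
    Re(conj(b_i) b_j) - Im S_ij Im(conj(b_i) b_j)]``.  Pairing these rows
    with :func:`hermitian_feature_matrix` turns batched quadratic forms into
    a single real GEMM — half the arithmetic of the complex route.
    """
    stack = np.asarray(stack, dtype=np.complex128)
    if stack.ndim == 2:
        stack = stack[None]
    n = stack.shape[-1]
    iu, ju = np.triu_indices(n, 1)
    diag = stack[:, np.arange(n), np.arange(n)].real
    off = stack[:, iu, ju]
    return np.ascontiguousarray(
        np.concatenate([diag, off.real, off.imag], axis=1)
    )


def hermitian_feature_matrix(vectors: np.ndarray) -> np.ndarray:
    """Real feature rows of excitation vectors matching
    :func:`hermitian_coeff_matrix` (``feats @ coeffs.T`` gives the forms)."""
    vectors = np.asarray(vectors, dtype=np.complex128)
    if vectors.ndim == 1:
        vectors = vectors[None]
    n = vectors.shape[-1]
    iu, ju = np.triu_indices(n, 1)
    z = vectors.conj()[:, iu] * vectors[:, ju]
    mag = (vectors.real**2 + vectors.imag**2)
    return np.ascontiguousarray(
        np.concatenate([mag, 2.0 * z.real, -2.0 * z.imag], axis=1)
    )


def max_sar_over_set(b: np.ndarray, sar_set: SARMatrixSet) -> tuple[float, int]:
    """Maximum local SAR over the set and the achieving voxel id.

    Ties are broken toward the smallest voxel id so reports are
    deterministic.
    """
    vals = quadratic_forms(sar_set.matrices, b)
    vmax = float(vals.max())
    ties = sar_set.voxel_ids[vals == vmax]
    return vmax, int(ties.min())


def worst_case_sar(sar_set: SARMatrixSet) -> float:
    """Supremum of local SAR over unit-power excitations.

    Equals the largest eigenvalue over all matrices in the set, since for
    unit-power ``b`` the quadratic form of a Hermitian matrix is maximised by
    its top eigenvector.
    """
    return float(sar_set.lambda_max().max())


def op_count(n_channels: int) -> tuple[int, int]:
    """Complex-arithmetic cost of one VOP SAR evaluation ``b'(S b)``.

    Counts the dense two-stage scheme: a matrix–vector product (``n**2``
    multiplications, ``n*(n-1)`` additions) followed by an inner product
    (``n`` multiplications, ``n-1`` additions).  Returns
    ``(multiplications, additions)``; at 8 channels this is ``(72, 63)``.
    """
    n = int(n_channels)
    if n < 1:
        raise ValueError(f"n_channels must be >= 1, got {n_channels}")
    mults = n * n + n
    adds = n * (n - 1) + (n - 1)
    return mults, adds
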