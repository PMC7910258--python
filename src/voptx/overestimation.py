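"""Overestimation terms for VOP compression.

The VOP condition bounds the true maximum local SAR by the maximum over a
small subset plus an *overestimation term* :math:`\\omega(b) \\ge 0`:

.. math::

    \\max_{v \\in V_{all}} b' S_v b \\;\\le\\;
    \\max_{w \\in V_{sub}} b' S_w b + \\omega(b)
    \\qquad \\forall b \\in \\mathbb{C}^{N_{ch}}.

Four interchangeable constructions of :math:`\\omega` are provided:

``global``
    :math:`\\omega(b) = \\varepsilon_G\\, b' S_{Global} b` — Lee's original
    choice; bounds the *absolute* overestimation but tracks local SAR only
    loosely, so the *relative* overestimation can explode at low SAR.
``diag``
    :math:`Z = d\\,I` with ``d`` the worst-case SAR; the term is exactly
    constant on the unit-power sphere (spectral-norm-style slack).
``local``
    :math:`Z = S_{local}`, a rough local-SAR approximant assembled from a
    VOP compression of a small random voxel sample (see
    :func:`build_s_local`), with eigenvalue spread compressed to at most 10
    by an exponent :math:`R \\ge 1`.
``double``
    the two-level term
    :math:`\\varepsilon_G (\\max_u b' S_u b + \\varepsilon_{G,pre}\\,
    b' S_{Global} b)` over a small pre-computed VOP set — the term itself
    *is* a SAR estimate, so the slack scales with actual SAR and the
    relative overestimation stays flat.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .model import (
    EmptySetError,
    SARMatrixSet,
    ShapeError,
    ValidationError,
    _check_hermitian,
    _check_psd,
    _hermitize,
    quadratic_forms,
    worst_case_sar,
)

__all__ = [
    "KINDS",
    "OverestimationModel",
    "SLocalBuildRecord",
    "build_s_diag",
    "build_s_global_approx",
    "select_R",
    "build_s_local",
    "evaluate_term",
    "build_model",
]

KINDS = ("global", "diag", "local", "double")

#: ratio bound the exponent R is chosen to enforce on the S_local eigenvalues
S_LOCAL_RATIO_BOUND = 10.0


@dataclasses.dataclass
class OverestimationModel:
    """The overestimation term :math:`\\omega(b)` of one strategy.

    Matrix-term kinds (``global``, ``diag``, ``local``) carry a Hermitian
    PSD matrix ``Z`` and evaluate ``epsilon_g * b'Zb``.  Kind ``double``
    carries the pre-computed VOP stack, its build factor ``epsilon_g_pre``
    and the global matrix, and evaluates
    ``epsilon_g * (max_u b'S_u b + epsilon_g_pre * b'S_Global b)``.
    """

    kind: str
    epsilon_g: float
    Z: Optional[np.ndarray] = None
    pre_vops: Optional[np.ndarray] = None
    epsilon_g_pre: Optional[float] = None
    global_matrix: Optional[np.ndarray] = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown overestimation kind {self.kind!r}")
        if self.epsilon_g < 0:
            raise ValidationError("epsilon_g must be >= 0")
        if self.kind == "double":
            if self.pre_vops is None or len(self.pre_vops) == 0:
                raise ValidationError("kind 'double' needs a nonempty pre-VOP set")
            if self.epsilon_g_pre is None or self.epsilon_g_pre < 0:
                raise ValidationError("kind 'double' needs epsilon_g_pre >= 0")
            if self.global_matrix is None:
                raise ValidationError("kind 'double' needs the global SAR matrix")
            self.pre_vops = np.asarray(self.pre_vops, dtype=np.complex128)
            self.global_matrix = np.asarray(self.global_matrix, dtype=np.complex128)
            if self.Z is not None:
                raise ValidationError("kind 'double' must not carry a Z matrix")
        else:
            if self.Z is None:
                raise ValidationError(f"kind {self.kind!r} needs a Z matrix")
            if self.pre_vops is not None:
                raise ValidationError(
                    f"kind {self.kind!r} must not carry pre-VOPs"
                )
            self.Z = np.asarray(self.Z, dtype=np.complex128)
            _check_hermitian(self.Z[None], "overestimation Z")
            _check_psd(self.Z[None], "overestimation Z")

    @property
    def n_channels(self) -> int:
        if self.kind == "double":
            return self.pre_vops.shape[-1]
        return self.Z.shape[-1]

    def pre_term_matrices(self) -> np.ndarray:
        """For ``double``: the stack ``S_u + epsilon_g_pre * S_Global``.

        The two-level term is ``epsilon_g * max_u b' (that stack)_u b``; the
        compression's dominance test and the baked export both consume this
        stack scaled by ``epsilon_g``.
        """
        if self.kind != "double":
            raise ValidationError("pre_term_matrices is only defined for 'double'")
        return self.pre_vops + self.epsilon_g_pre * self.global_matrix[None]

    def term(self, b: np.ndarray) -> float:
        """:math:`\\omega(b)` for a single excitation vector."""
        return float(self.term_many(np.asarray(b, dtype=np.complex128)[None])[0])

    def term_many(self, vectors: np.ndarray) -> np.ndarray:
        """:math:`\\omega(b)` for a batch of vectors, shape ``(m, n_ch)``."""
        vectors = np.asarray(vectors, dtype=np.complex128)
        if vectors.ndim != 2 or vectors.shape[1] != self.n_channels:
            raise ShapeError(
                f"expected vectors of shape (m, {self.n_channels}); "
                f"got {vectors.shape}"
            )
        if self.kind == "double":
            stack = self.pre_term_matrices()
            per = np.einsum(
                "mi,uij,mj->mu", vectors.conj(), stack, vectors
            ).real
            return self.epsilon_g * per.max(axis=1)
        vals = np.einsum(
            "mi,ij,mj->m", vectors.conj(), self.Z, vectors
        ).real
        return self.epsilon_g * vals


def evaluate_term(model: OverestimationModel, b: np.ndarray) -> float:
    """Evaluate the overestimation term :math:`\\omega(b)`."""
    return model.term(b)


# ---------------------------------------------------------------------------
# matrix constructions
# ---------------------------------------------------------------------------

def build_s_diag(sar_set: SARMatrixSet) -> np.ndarray:
    """``d * I`` with ``d`` the worst-case local SAR of the set.

    For any unit-power ``b``, ``b'(dI)b = d`` exactly, so the resulting
    overestimation term is constant over the unit-power sphere.
    """
    d = worst_case_sar(sar_set)
    return d * np.eye(sar_set.n_channels, dtype=np.complex128)


def build_s_global_approx(
    sar_set: SARMatrixSet, weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """Weight-normalised sum of all matrices — an S_Global surrogate.

    Used only when the input container supplies no true global-SAR matrix;
    uniform weights by default.
    """
    if weights is None:
        return np.mean(sar_set.matrices, axis=0)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (sar_set.n_voxels,):
        raise ShapeError("weights length must equal the number of matrices")
    if np.any(weights < 0):
        raise ValidationError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("weights must not all be zero")
    return np.tensordot(weights / total, sar_set.matrices, axes=1)


def select_R(eig_sars: np.ndarray) -> float:
    """Smallest exponent ``R >= 1`` with ``(max/min)**(1/R) <= 10``.

    Closed form: ``R = max(1, log10(max/min))``.  Raising each
    eigenvector-SAR to ``1/R`` then compresses the spread of the S_local
    eigenvalues to the ratio bound.
    """
    vals = np.asarray(eig_sars, dtype=float)
    if vals.size == 0:
        raise EmptySetError("eig_sars must be nonempty")
    if np.any(vals <= 0):
        raise ValidationError(
            "eigenvector SAR values must be strictly positive "
            "(a zero would make the scaled diagonal degenerate)"
        )
    ratio = float(vals.max() / vals.min())
    return max(1.0, math.log10(ratio))


@dataclasses.dataclass
class SLocalBuildRecord:
    """Provenance of one S_local construction.

    Stores the random-sample fraction, the inner-compression overestimation
    factor, the summed pre-matrix ``S_pre``, its eigenvectors, the
    eigenvector SAR values measured against the *full* set, the exponent
    ``R`` and the scaled diagonal ``d``.
    """

    subset_fraction: float
    pre_epsilon: float
    s_pre: np.ndarray
    eigvecs: np.ndarray
    eig_sars: np.ndarray
    R: float
    d: np.ndarray
    n_sample: int = 0
    n_pre_vops: int = 0
    floored: bool = False
    seed: int = 0


def build_s_local(
    sar_set: SARMatrixSet,
    subset_fraction: float = 0.01,
    pre_epsilon: float = 0.2,
    seed: int = 0,
    eig_floor: float = 1e-6,
    config=None,
) -> tuple[np.ndarray, SLocalBuildRecord]:
    """Construct the local-SAR-approximating overestimation matrix.

    Pipeline: (i) draw a seeded uniform random sample of
    ``ceil(subset_fraction * n_voxels)`` voxels without replacement;
    (ii) compress the sample with the ``global`` strategy at
    ``pre_epsilon``; (iii) sum the resulting VOP matrices into ``S_pre``;
    (iv) eigendecompose ``S_pre``; (v) measure the maximum local SAR of each
    eigenvector against the *full* set; (vi) compress the spread with
    exponent ``R`` from :func:`select_R`; (vii) reassemble
    ``S_local = V diag(d) V'``.

    Eigenvector SARs of (numerically) zero are floored at
    ``eig_floor * max`` before the exponent is applied, keeping the scaled
    diagonal positive definite; the flooring is flagged in the record.
    """
    from .compress import CompressionConfig, compress  # local import: cycle

    if not (0 < subset_fraction <= 1):
        raise ValidationError("subset_fraction must lie in (0, 1]")
    if pre_epsilon <= 0:
        raise ValidationError("pre_epsilon must be > 0")
    n_sample = math.ceil(subset_fraction * sar_set.n_voxels)
    if n_sample < 1:
        raise EmptySetError("sample smaller than one voxel")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(sar_set.n_voxels, size=n_sample, replace=False))
    sample = sar_set.subset(pos)

    s_global = (
        sar_set.global_matrix
        if sar_set.global_matrix is not None
        else build_s_global_approx(sar_set)
    )
    if config is None:
        cfg = CompressionConfig(seed=seed)
    else:
        cfg = dataclasses.replace(config, seed=seed, epsilon_g=None)
    inner_model = OverestimationModel("global", pre_epsilon, Z=s_global)
    result = compress(sample, inner_model, cfg)
    if result.n_vops == 0:
        raise EmptySetError("inner compression yielded no VOPs")

    s_pre = _hermitize(result.vop_matrices.sum(axis=0))
    _evals, eigvecs = np.linalg.eigh(s_pre)

    eig_sars = np.empty(sar_set.n_channels)
    for i in range(sar_set.n_channels):
        eig_sars[i] = quadratic_forms(sar_set.matrices, eigvecs[:, i]).max()
    floored = bool(np.any(eig_sars < eig_floor * eig_sars.max()))
    eig_sars_f = np.maximum(eig_sars, eig_floor * eig_sars.max())

    R = select_R(eig_sars_f)
    d = eig_sars_f ** (1.0 / R)
    s_local = _hermitize((eigvecs * d) @ eigvecs.conj().T)
    record = SLocalBuildRecord(
        subset_fraction=subset_fraction,
        pre_epsilon=pre_epsilon,
        s_pre=s_pre,
        eigvecs=eigvecs,
        eig_sars=eig_sars_f,
        R=R,
        d=d,
        n_sample=n_sample,
        n_pre_vops=result.n_vops,
        floored=floored,
        seed=seed,
    )
    return s_local, record


# ---------------------------------------------------------------------------
# strategy factory
# ---------------------------------------------------------------------------

def build_model(
    sar_set: SARMatrixSet,
    kind: str,
    epsilon_g: float,
    *,
    seed: int = 0,
    subset_fraction: float = 0.01,
    s_local_pre_epsilon: float = 0.2,
    pre_epsilon: float = 0.2,
    pre_target_count: int = 10,
    pre_auto_tune: bool = True,
    config=None,
) -> OverestimationModel:
    """Build the overestimation model of a named strategy for a set.

    ``global`` uses the set's S_Global (or the uniform-sum surrogate when
    absent), ``diag`` the worst-case diagonal, ``local`` the full
    :func:`build_s_local` pipeline, and ``double`` first pre-computes a
    small VOP set (auto-tuning ``epsilon_g_pre`` toward at most
    ``pre_target_count`` pre-VOPs by default).
    """
    from .compress import precompute_vops  # local import: cycle

    if kind == "diag":
        return OverestimationModel("diag", epsilon_g, Z=build_s_diag(sar_set))
    s_global = (
        sar_set.global_matrix
        if sar_set.global_matrix is not None
        else build_s_global_approx(sar_set)
    )
    if kind == "global":
        meta = {} if sar_set.global_matrix is not None else {"approximate": True}
        return OverestimationModel("global", epsilon_g, Z=s_global, metadata=meta)
    if kind == "local":
        s_local, record = build_s_local(
            sar_set,
            subset_fraction=subset_fraction,
            pre_epsilon=s_local_pre_epsilon,
            seed=seed,
            config=config,
        )
        return OverestimationModel(
            "local", epsilon_g, Z=s_local, metadata={"build_record": record}
        )
    if kind == "double":
        pre, eps_used, trace = precompute_vops(
            sar_set,
            pre_epsilon,
            target_count=pre_target_count,
            auto_tune=pre_auto_tune,
            seed=seed,
            config=config,
        )
        return OverestimationModel(
            "double",
            epsilon_g,
            pre_vops=pre,
            epsilon_g_pre=eps_used,
            global_matrix=s_global,
            metadata={"pre_trace": trace},
        )
    raise ValidationError(f"unknown strategy kind {kind!r}")
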