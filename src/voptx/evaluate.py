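"""Random-excitation evaluation of compressed VOP sets.

The safety and tightness of a compression are measured the way supervision
systems are validated: draw a large batch of random unit-power excitation
vectors, compute for each the *actual* maximum local SAR from the
uncompressed set and the VOP-bounded SAR from the baked VOP collections,
and summarise the overestimation.  A single underestimation anywhere is a
hard error — the no-underestimation guarantee is the whole point of the
certificates.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import EmptySetError, SARMatrixSet, ShapeError
from .compress import CompressionConfig, VOPResult, bound_many, compress
from .overestimation import build_model

__all__ = [
    "SafetyError",
    "EvaluationReport",
    "ComparisonCurve",
    "random_unit_power_vectors",
    "actual_max_sar",
    "evaluate_compression",
    "comparison_curve",
]


class SafetyError(RuntimeError):
    """The VOP bound fell below the actual SAR for some excitation vector."""


def random_unit_power_vectors(n: int, channels: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` isotropic random excitation vectors of unit power.

    Entries are independent standard complex Gaussians, then each vector is
    normalised to squared 2-norm 1; the direction law is invariant under any
    fixed unitary channel rotation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, channels)) + 1j * rng.standard_normal((n, channels))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a numerically zero draw is astronomically unlikely; guard anyway
    norms[norms == 0] = 1.0
    return v / norms


def actual_max_sar(
    sar_set: SARMatrixSet,
    vectors: np.ndarray,
    chunk_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vector maximum local SAR over the full set, with argmax voxel ids.

    Evaluated in chunks of vectors via one complex GEMM per chunk
    (``b'Sb = <vec(S), vec(b b')>``); the per-vector maximum is independent
    of the chunking, so chunked execution is bit-identical.
    """
    vectors = np.asarray(vectors, dtype=np.complex128)
    if vectors.ndim != 2 or vectors.shape[1] != sar_set.n_channels:
        raise ShapeError(
            f"expected vectors of shape (m, {sar_set.n_channels}); "
            f"got {vectors.shape}"
        )
    from .model import hermitian_coeff_matrix, hermitian_feature_matrix

    # packed Hermitian representation: one real GEMM per chunk
    coeffs_t = np.ascontiguousarray(hermitian_coeff_matrix(sar_set.matrices).T)
    out = np.empty(len(vectors))
    arg = np.empty(len(vectors), dtype=np.int64)
    for lo in range(0, len(vectors), chunk_size):
        chunk = vectors[lo : lo + chunk_size]
        vals = hermitian_feature_matrix(chunk) @ coeffs_t
        idx = np.argmax(vals, axis=1)
        out[lo : lo + len(chunk)] = vals[np.arange(len(chunk)), idx]
        arg[lo : lo + len(chunk)] = sar_set.voxel_ids[idx]
    return out, arg


@dataclasses.dataclass
class EvaluationReport:
    """Summary of a random-vector safety evaluation."""

    n_vectors: int
    actual_sar: np.ndarray
    vop_sar: np.ndarray
    max_relative_overestimation: float  # percent
    max_absolute_overestimation: float  # W/kg
    argmax_vector_index: int
    underestimation_count: int
    seed: int
    metadata: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-vector table (actual, bound, overestimations)."""
        over = self.vop_sar - self.actual_sar
        return pd.DataFrame(
            {
                "vector_index": np.arange(self.n_vectors),
                "actual_sar": self.actual_sar,
                "vop_sar": self.vop_sar,
                "absolute_overestimation": over,
                "relative_overestimation_pct": 100.0 * over / self.actual_sar,
            }
        )


def evaluate_compression(
    sar_set: SARMatrixSet,
    result: VOPResult,
    vectors: np.ndarray,
    actual: Optional[np.ndarray] = None,
    rel_tol: float = 1e-9,
    seed: int = 0,
    chunk_size: int = 4096,
) -> EvaluationReport:
    """Compare the VOP bound against the uncompressed set on given vectors.

    ``actual`` may be passed in to reuse the (expensive) full-set maxima
    across several compressions of the same set and probe batch.  Raises
    :class:`SafetyError` on any underestimation beyond the relative
    tolerance, naming the first offending vector and voxel.
    """
    vectors = np.asarray(vectors, dtype=np.complex128)
    if sar_set.n_channels != result.vop_matrices.shape[-1]:
        raise ShapeError("set and compression channel counts differ")
    if actual is None:
        actual, arg_ids = actual_max_sar(sar_set, vectors, chunk_size)
    else:
        actual = np.asarray(actual, dtype=float)
        arg_ids = None
    vop = bound_many(result, vectors)

    deficit = actual - vop
    bad = deficit > rel_tol * np.abs(actual)
    count = int(bad.sum())
    if count:
        i = int(np.argmax(deficit / np.maximum(np.abs(actual), 1e-300)))
        if arg_ids is None:
            _, arg_ids_i = actual_max_sar(sar_set, vectors[i : i + 1])
            voxel = int(arg_ids_i[0])
        else:
            voxel = int(arg_ids[i])
        raise SafetyError(
            f"underestimation at vector {i} (voxel {voxel}): "
            f"actual {actual[i]:.6e} > bound {vop[i]:.6e}"
        )

    over = vop - actual
    rel = 100.0 * over / actual
    i_max = int(np.argmax(rel))
    return EvaluationReport(
        n_vectors=len(vectors),
        actual_sar=actual,
        vop_sar=vop,
        max_relative_overestimation=float(rel[i_max]),
        max_absolute_overestimation=float(over.max()),
        argmax_vector_index=i_max,
        underestimation_count=count,
        seed=seed,
        metadata={
            "strategy": result.strategy_tag,
            "n_vops": result.n_vops,
            "n_pre_vops": result.n_pre_vops,
            "vector_law": "isotropic complex Gaussian direction, unit power",
        },
    )


@dataclasses.dataclass
class ComparisonCurve:
    """One strategy's (epsilon_g, n_vops, max relative overestimation) curve.

    ``n_vops`` counts pre-VOPs for the Double-VOP strategy, since the
    supervision system has to evaluate both collections.  Points are sorted
    by ``n_vops``.
    """

    strategy_tag: str
    points: list  # of (epsilon_g, n_vops, max_relative_overestimation_pct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points,
            columns=["epsilon_g", "n_vops", "max_relative_overestimation_pct"],
        ).assign(strategy=self.strategy_tag)


def comparison_curve(
    sar_set: SARMatrixSet,
    strategies: Sequence[str],
    epsilon_grid: Sequence[float],
    seeds: Sequence[int] = (0,),
    n_vectors: int = 10_000,
    probe_seed: int = 1234,
    config: Optional[CompressionConfig] = None,
    model_kwargs: Optional[dict] = None,
) -> tuple[list[ComparisonCurve], pd.DataFrame]:
    """Sweep strategies over an epsilon grid and evaluate each compression.

    The probe vectors and the full-set actual SAR are computed once per
    seed and reused across every (strategy, epsilon) cell.  Per-strategy
    fixed structures (the S_local matrix, the pre-VOP set) are built once
    per seed as well, so the grid varies only the final compression factor.
    Returns one curve per (strategy, seed) plus a tidy long-format table.
    """
    if len(epsilon_grid) == 0:
        raise EmptySetError("epsilon_grid must be nonempty")
    model_kwargs = dict(model_kwargs or {})
    base = config if config is not None else CompressionConfig()
    curves: list[ComparisonCurve] = []
    rows = []
    for seed in seeds:
        vectors = random_unit_power_vectors(n_vectors, sar_set.n_channels, probe_seed + seed)
        actual, _ = actual_max_sar(sar_set, vectors)
        for strat in strategies:
            points = []
            # fixed per-strategy structure at a reference epsilon; the
            # model is rebuilt per grid point only in its scalar factor
            proto = build_model(
                sar_set, strat, float(epsilon_grid[0]), seed=seed,
                config=base, **model_kwargs
            )
            for eps in epsilon_grid:
                model = dataclasses.replace(proto, epsilon_g=float(eps))
                cfg = dataclasses.replace(base, epsilon_g=None, seed=seed)
                result = compress(sar_set, model, cfg)
                report = evaluate_compression(
                    sar_set, result, vectors, actual=actual, seed=probe_seed + seed
                )
                n_total = result.n_vops + result.n_pre_vops
                points.append(
                    (float(eps), n_total, report.max_relative_overestimation)
                )
                rows.append(
                    {
                        "strategy": strat,
                        "seed": seed,
                        "epsilon_g": float(eps),
                        "n_vops": result.n_vops,
                        "n_pre_vops": result.n_pre_vops,
                        "n_vops_total": n_total,
                        "max_relative_overestimation_pct": report.max_relative_overestimation,
                        "max_absolute_overestimation": report.max_absolute_overestimation,
                    }
                )
            points.sort(key=lambda p: p[1])
            curves.append(ComparisonCurve(strategy_tag=strat, points=points))
    return curves, pd.DataFrame(rows)
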