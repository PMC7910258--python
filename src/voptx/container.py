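"""HDF5 container for SAR matrix sets and attached results.

Layout (format version 1)::

    /matrices        complex (n_vox, n_ch, n_ch), chunked + gzip
    /voxel_ids       int64  (n_vox,)
    /global_matrix   complex (n_ch, n_ch)            [optional]
    /vops            group: indices, matrices, baked collections, model
    /overestimation  group: kind, epsilons, Z, pre-VOPs, S_local build record
    /evaluation      group: per-run summary scalars + per-vector arrays
    attrs: format_version, n_channels, units, provenance (JSON)

Complex data uses h5py's native compound complex convention; separate
``<name>_real`` / ``<name>_imag`` dataset pairs are auto-detected on read as
a fallback.  Matrices are symmetrized on load (with a warning if the
asymmetry exceeds the Hermitian tolerance) and fully validated — a
container that fails validation raises, it never yields a partial object.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Optional

import h5py
import numpy as np

from .model import SARMatrixSet, ValidationError
from .compress import CompressionConfig, VOPResult, bake_vops
from .evaluate import EvaluationReport
from .overestimation import OverestimationModel, SLocalBuildRecord

__all__ = [
    "FORMAT_VERSION",
    "ContainerFormatError",
    "write_container",
    "read_container",
    "read_attached_vops",
    "append_vops",
    "append_report",
    "iter_matrix_chunks",
    "load_matlab_sar_matrices",
]

FORMAT_VERSION = 1
UNITS = "W/kg per unit input power"


class ContainerFormatError(ValidationError):
    """The file is not a valid (or supported) SAR container."""


def _write_complex(group: h5py.Group, name: str, data: np.ndarray, **kw) -> None:
    group.create_dataset(name, data=np.asarray(data, dtype=np.complex128), **kw)


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    if name in group:
        return np.asarray(group[name], dtype=np.complex128)
    if f"{name}_real" in group and f"{name}_imag" in group:
        return np.asarray(group[f"{name}_real"], dtype=float) + 1j * np.asarray(
            group[f"{name}_imag"], dtype=float
        )
    raise ContainerFormatError(f"missing dataset {name!r} in {group.name!r}")


def write_container(
    path,
    sar_set: SARMatrixSet,
    *,
    vop_result: Optional[VOPResult] = None,
    report: Optional[EvaluationReport] = None,
    chunk_voxels: int = 1024,
    mode: str = "w",
) -> None:
    """Write a matrix set (and optional results) to an HDF5 container."""
    path = Path(path)
    n_vox, n = sar_set.n_voxels, sar_set.n_channels
    chunk = (min(chunk_voxels, n_vox), n, n)
    with h5py.File(path, mode) as f:
        _write_complex(
            f, "matrices", sar_set.matrices, chunks=chunk, compression="gzip"
        )
        f.create_dataset("voxel_ids", data=sar_set.voxel_ids)
        if sar_set.global_matrix is not None:
            _write_complex(f, "global_matrix", sar_set.global_matrix)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_channels"] = n
        f.attrs["units"] = UNITS
        f.attrs["provenance"] = json.dumps(sar_set.metadata, default=_json_default)
    if vop_result is not None:
        append_vops(path, vop_result)
    if report is not None:
        append_report(path, report)


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return {
            f.name: getattr(obj, f.name)
            for f in dataclasses.fields(obj)
            if not isinstance(getattr(obj, f.name), np.ndarray)
        }
    return str(obj)


def read_container(path, validate: bool = True) -> SARMatrixSet:
    """Read and validate a container into a :class:`SARMatrixSet`.

    Validation failures (missing datasets, shape mismatch, non-Hermitian or
    non-PSD matrices beyond tolerance) are errors, never warnings.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerFormatError(f"cannot open {path}: {exc}") from exc
    with f:
        if "format_version" not in f.attrs:
            raise ContainerFormatError(f"{path} has no format_version attribute")
        version = int(f.attrs["format_version"])
        if version > FORMAT_VERSION:
            raise ContainerFormatError(
                f"unsupported container format version {version}"
            )
        matrices = _read_complex(f, "matrices")
        if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
            raise ContainerFormatError(
                f"/matrices has invalid shape {matrices.shape}"
            )
        if "voxel_ids" in f:
            voxel_ids = np.asarray(f["voxel_ids"], dtype=np.int64)
        else:
            voxel_ids = None
        try:
            global_matrix = _read_complex(f, "global_matrix")
        except ContainerFormatError:
            global_matrix = None
        meta = {}
        if "provenance" in f.attrs:
            try:
                meta = json.loads(f.attrs["provenance"])
            except (TypeError, json.JSONDecodeError):
                meta = {"provenance_raw": str(f.attrs["provenance"])}
    try:
        return SARMatrixSet(
            matrices,
            voxel_ids=voxel_ids,
            global_matrix=global_matrix,
            metadata=meta,
            validate=validate,
            symmetrize=True,
        )
    except ValidationError as exc:
        raise ContainerFormatError(f"{path}: {exc}") from exc


def append_vops(path, result: VOPResult) -> None:
    """Append (or replace) the ``/vops`` and ``/overestimation`` groups."""
    with h5py.File(path, "a") as f:
        for name in ("vops", "overestimation"):
            if name in f:
                del f[name]
        g = f.create_group("vops")
        g.create_dataset("indices", data=np.asarray(result.vop_indices))
        g.create_dataset("positions", data=np.asarray(result.vop_positions))
        _write_complex(g, "matrices", result.vop_matrices)
        for i, stack in enumerate(bake_vops(result)):
            _write_complex(g, f"baked_{i}", stack)
        g.attrs["strategy_tag"] = result.strategy_tag
        g.attrs["n_voxels"] = result.n_voxels
        g.attrs["config"] = json.dumps(
            dataclasses.asdict(result.config), default=_json_default
        )
        if result.certificates:
            certs = g.create_group("certificates")
            for vid, cert in result.certificates.items():
                cg = certs.create_group(str(vid))
                cg.create_dataset("c_vop", data=np.asarray(cert["c_vop"]))
                cg.create_dataset("c_pre", data=np.asarray(cert["c_pre"]))
                cg.attrs["n_vops_at_cert"] = cert["n_vops_at_cert"]

        model = result.model
        o = f.create_group("overestimation")
        o.attrs["kind"] = model.kind
        o.attrs["epsilon_g"] = model.epsilon_g
        if model.kind == "double":
            o.attrs["epsilon_g_pre"] = model.epsilon_g_pre
            _write_complex(o, "pre_vops", model.pre_vops)
            _write_complex(o, "global_matrix", model.global_matrix)
        else:
            _write_complex(o, "Z", model.Z)
        record = model.metadata.get("build_record")
        if isinstance(record, SLocalBuildRecord):
            rg = o.create_group("s_local_build")
            _write_complex(rg, "s_pre", record.s_pre)
            _write_complex(rg, "eigvecs", record.eigvecs)
            rg.create_dataset("eig_sars", data=record.eig_sars)
            rg.create_dataset("d", data=record.d)
            for key in (
                "subset_fraction",
                "pre_epsilon",
                "R",
                "n_sample",
                "n_pre_vops",
                "floored",
                "seed",
            ):
                rg.attrs[key] = getattr(record, key)


def read_attached_vops(path) -> VOPResult:
    """Reload a ``/vops`` + ``/overestimation`` pair as a :class:`VOPResult`."""
    with h5py.File(path, "r") as f:
        if "vops" not in f or "overestimation" not in f:
            raise ContainerFormatError(f"{path} carries no compression results")
        g, o = f["vops"], f["overestimation"]
        kind = str(o.attrs["kind"])
        eps = float(o.attrs["epsilon_g"])
        if kind == "double":
            model = OverestimationModel(
                kind,
                eps,
                pre_vops=_read_complex(o, "pre_vops"),
                epsilon_g_pre=float(o.attrs["epsilon_g_pre"]),
                global_matrix=_read_complex(o, "global_matrix"),
            )
        else:
            model = OverestimationModel(kind, eps, Z=_read_complex(o, "Z"))
        cfg_raw = json.loads(g.attrs["config"])
        cfg = CompressionConfig(
            **{
                k: v
                for k, v in cfg_raw.items()
                if k in {f.name for f in dataclasses.fields(CompressionConfig)}
            }
        )
        certificates = {}
        if "certificates" in g:
            for vid, cg in g["certificates"].items():
                certificates[int(vid)] = {
                    "c_vop": np.asarray(cg["c_vop"]),
                    "c_pre": np.asarray(cg["c_pre"]),
                    "n_vops_at_cert": int(cg.attrs["n_vops_at_cert"]),
                }
        return VOPResult(
            vop_indices=np.asarray(g["indices"]),
            vop_positions=np.asarray(g["positions"]),
            vop_matrices=_read_complex(g, "matrices"),
            model=model,
            config=cfg,
            strategy_tag=str(g.attrs["strategy_tag"]),
            n_voxels=int(g.attrs["n_voxels"]),
            certificates=certificates,
        )


def append_report(path, report: EvaluationReport, name: str = "latest") -> None:
    """Append an evaluation report under ``/evaluation/<name>``."""
    with h5py.File(path, "a") as f:
        g = f.require_group("evaluation")
        if name in g:
            del g[name]
        r = g.create_group(name)
        r.create_dataset("actual_sar", data=report.actual_sar)
        r.create_dataset("vop_sar", data=report.vop_sar)
        for key in (
            "n_vectors",
            "max_relative_overestimation",
            "max_absolute_overestimation",
            "argmax_vector_index",
            "underestimation_count",
            "seed",
        ):
            r.attrs[key] = getattr(report, key)
        r.attrs["metadata"] = json.dumps(report.metadata, default=_json_default)


def iter_matrix_chunks(
    path, chunk_size: int = 4096
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream ``(voxel_ids, matrices)`` chunks without loading the full stack.

    Reads directly from the chunked dataset, holding at most ``chunk_size``
    matrices in memory at a time.
    """
    with h5py.File(path, "r") as f:
        dset = f["matrices"]
        ids = np.asarray(f["voxel_ids"]) if "voxel_ids" in f else np.arange(dset.shape[0])
        for lo in range(0, dset.shape[0], chunk_size):
            hi = min(lo + chunk_size, dset.shape[0])
            yield ids[lo:hi], np.asarray(dset[lo:hi], dtype=np.complex128)


def load_matlab_sar_matrices(path, validate: bool = True) -> SARMatrixSet:
    """Best-effort import of SAR matrices from a MATLAB ``.mat`` file.

    Accepts any variable holding a complex array shaped ``(n, n, n_vox)``
    (MATLAB's natural stacking) or ``(n_vox, n, n)``; the largest matching
    variable wins.  Goes through the same validation gate as the native
    container.
    """
    from scipy.io import loadmat

    try:
        data = loadmat(path)
    except (OSError, ValueError, NotImplementedError) as exc:
        raise ContainerFormatError(f"cannot read {path} as a .mat file: {exc}") from exc
    best = None
    for key, val in data.items():
        if key.startswith("__") or not isinstance(val, np.ndarray) or val.ndim != 3:
            continue
        if val.shape[0] == val.shape[1]:
            stack = np.moveaxis(val, 2, 0)
        elif val.shape[1] == val.shape[2]:
            stack = val
        else:
            continue
        if best is None or stack.shape[0] > best.shape[0]:
            best = stack
    if best is None:
        raise ContainerFormatError(
            f"{path}: no 3-D square-matrix stack variable found"
        )
    return SARMatrixSet(
        np.asarray(best, dtype=np.complex128),
        metadata={"source": str(path), "importer": "load_matlab_sar_matrices"},
        validate=validate,
        symmetrize=True,
    )
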