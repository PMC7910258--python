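"""Shared fixtures: small random Hermitian-PSD sets and synthetic phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from voptx import ArrayPhantomSpec, SARMatrixSet, generate_sar_set, worked_toy_set


def random_psd_stack(
    rng: np.random.Generator, n_vox: int, n_ch: int, rank: int | None = None
) -> np.ndarray:
    """Random Hermitian PSD matrices as A A' with complex Gaussian factors."""
    r = rank or n_ch
    a = rng.standard_normal((n_vox, n_ch, r)) + 1j * rng.standard_normal(
        (n_vox, n_ch, r)
    )
    return np.einsum("vik,vjk->vij", a, a.conj()) / r


def random_set(
    seed: int, n_vox: int, n_ch: int, rank: int | None = None, with_global=True
) -> SARMatrixSet:
    rng = np.random.default_rng(seed)
    mats = random_psd_stack(rng, n_vox, n_ch, rank)
    g = mats.mean(axis=0) if with_global else None
    return SARMatrixSet(mats, global_matrix=g)


@pytest.fixture(scope="session")
def small_set() -> SARMatrixSet:
    """300 random 4-channel matrices — the brute-force-oracle scale."""
    return random_set(seed=7, n_vox=300, n_ch=4)


@pytest.fixture(scope="session")
def toy_set() -> SARMatrixSet:
    return worked_toy_set()


@pytest.fixture(scope="session")
def phantom_4ch() -> SARMatrixSet:
    """Small synthetic 4-channel phantom with hot-spot structure."""
    return generate_sar_set(
        ArrayPhantomSpec(n_channels=4, grid_shape=(10, 10, 14), seed=11)
    )


@pytest.fixture(scope="session")
def phantom_8ch() -> SARMatrixSet:
    """Reduced-grid 8-channel phantom (fast; keeps the default physics)."""
    return generate_sar_set(ArrayPhantomSpec(grid_shape=(12, 12, 20), seed=5))
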