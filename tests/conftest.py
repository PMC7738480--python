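"""Shared fixtures: phantoms, mock plane models, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cpseg.phantoms import PhantomSpec, generate_phantom

TISSUE_OF_LABEL = np.array([0, 1, 1, 2, 2])  # bg / inner / plate


@pytest.fixture(scope="session")
def phantom48():
    """One folded phantom on a 48^3 grid, no noise (geometry tests)."""
    spec = PhantomSpec.default(grid=48, noise_sd=0.0, blur_fwhm_mm=0.0)
    return generate_phantom(spec, complexity=0.5)


@pytest.fixture(scope="session")
def phantom64():
    """One realistic phantom on a 64^3 grid (blur + noise)."""
    spec = PhantomSpec.default(grid=64, seed=7)
    return generate_phantom(spec, complexity=0.5)


class SideAwareMock:
    """Pointwise mock plane model: label = tissue(value) + displayed side.

    The input intensity is expected to carry the tissue code (the label
    volume cast to float). The mock assigns the left/right label variant
    from the pixel's displayed horizontal position, which makes it exactly
    flip-equivariant including the left-right label swap - the behavior an
    ideally trained network would have. Calls are counted so aggregation
    paths can be audited.
    """

    def __init__(self, n_labels: int = 5, plane: str = "axial"):
        self.n_labels = n_labels
        self.plane = plane
        self.calls = 0
        self.slices_seen = 0

    def __call__(self, slices: np.ndarray) -> np.ndarray:
        self.calls += 1
        self.slices_seen += len(slices)
        n, h, w = slices.shape
        tissue = TISSUE_OF_LABEL[np.clip(np.rint(slices).astype(int), 0, 4)]
        out = np.zeros((n, self.n_labels, h, w), dtype=np.float32)
        if self.n_labels == 3:
            for t in range(3):
                out[:, t][tissue == t] = 1.0
            return out
        # horizontal axis is axis 1 of the slice; left half -> left labels
        col = np.arange(h)[None, :, None]
        left = np.broadcast_to(col < h / 2, (n, h, w))
        out[:, 0][tissue == 0] = 1.0
        out[:, 1][(tissue == 1) & left] = 1.0
        out[:, 2][(tissue == 1) & ~left] = 1.0
        out[:, 3][(tissue == 2) & left] = 1.0
        out[:, 4][(tissue == 2) & ~left] = 1.0
        return out


@pytest.fixture
def mock_models():
    return {
        "axial": SideAwareMock(5, "axial"),
        "coronal": SideAwareMock(5, "coronal"),
        "sagittal": SideAwareMock(3, "sagittal"),
    }


def brute_force_erosion(x: np.ndarray, offsets) -> np.ndarray:
    """Reference grayscale erosion: explicit min over disk offsets, replicate border."""
    h, w = x.shape
    out = np.empty_like(x)
    for i in range(h):
        for j in range(w):
            lo = np.inf
            for di, dj in offsets:
                ii = min(max(i + di, 0), h - 1)
                jj = min(max(j + dj, 0), w - 1)
                lo = min(lo, x[ii, jj])
            out[i, j] = lo
    return out


def brute_force_msd(a_mask: np.ndarray, b_mask: np.ndarray, voxel_mm: float) -> float:
    """Reference symmetric MSD: all-pairs distances between boundary voxels."""
    from cpseg.metrics import boundary_voxels

    pa = np.argwhere(boundary_voxels(a_mask)) * voxel_mm
    pb = np.argwhere(boundary_voxels(b_mask)) * voxel_mm
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())
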