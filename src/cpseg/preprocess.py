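"""Image conditioning and volume <-> slice-stack plumbing.

Volumes live on an RAS-ordered grid with array axes (x, y, z) =
(left-right, anterior-posterior, superior-inferior). Plane conventions:

==========  ===========  ==========================================
plane       stack axis   in-plane axes (horizontal, vertical)
==========  ===========  ==========================================
axial       z            (x, y)   horizontal = left-right
coronal     y            (x, z)   horizontal = left-right
sagittal    x            (y, z)   no left-right axis in plane
==========  ===========  ==========================================

"Horizontal flip" therefore swaps left and right exactly for axial and
coronal slices, which is what makes flip augmentation with label swapping
well defined. Conditioning mirrors the acquisition pipeline: multiply by
the brain mask, z-score the in-mask intensities, crop each plane to the
brain bounding box and zero-pad symmetrically to a fixed square slice
(128 x 128 for the full-scale model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

#: plane -> (stack axis, (horizontal in-plane axis, vertical in-plane axis))
PLANES: dict = {"axial": (2, (0, 1)), "coronal": (1, (0, 2)), "sagittal": (0, (1, 2))}

#: 5-label -> 3-label collapse used for sagittal slices
SAGITTAL_LABEL_MAP = np.array([0, 1, 1, 2, 2], dtype=np.uint8)


@dataclass
class SliceGeometry:
    """Everything needed to invert slicing: crop box, padding, axis order."""

    plane: str
    orig_shape: tuple
    crop_lo: tuple  # in-plane crop starts (half-open boxes, 0-based)
    crop_hi: tuple
    pad_lo: tuple  # symmetric zero-padding offsets inside the slice
    slice_size: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SliceGeometry":
        d = json.loads(s)
        for k in ("orig_shape", "crop_lo", "crop_hi", "pad_lo"):
            d[k] = tuple(d[k])
        return cls(**d)

    def write(self, path: str | Path):
        Path(path).write_text(self.to_json())


@dataclass
class SliceStack:
    """Ordered square slices of one plane plus the geometry to invert them."""

    plane: str
    slices: np.ndarray  # (n_slices, slice_size, slice_size)
    geometry: SliceGeometry
    label_scheme: int | None = None  # 5, 3, or None for intensity stacks

    def __len__(self) -> int:
        return len(self.slices)


def apply_brain_mask(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every voxel outside the binary brain mask."""
    vol, mask = np.asarray(vol), np.asarray(mask)
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    umask = np.unique(mask)
    if not np.all(np.isin(umask, (0, 1))):
        raise ValueError("mask must be binary")
    return (vol * (mask > 0)).astype(np.float32)


def zscore_normalize(vol: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score the intensities over the normalization support.

    The support is the in-mask region if a mask is given, else the nonzero
    voxels (masked scans are zero outside the brain, and including that
    background would let it dominate the statistics). Out-of-support voxels
    are left at zero, the post-transform background level.
    """
    vol = np.asarray(vol, dtype=np.float32)
    support = (mask > 0) if mask is not None else (vol != 0)
    vals = vol[support]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("z-transform undefined: <2 distinct values in support")
    out = np.zeros_like(vol)
    out[support] = (vals - vals.mean()) / vals.std()
    return out


def _bbox(mask: np.ndarray, axis_pair: tuple) -> tuple:
    nz = np.nonzero(mask)
    lo, hi = [], []
    for ax in axis_pair:
        if nz[ax].size == 0:
            lo.append(0)
            hi.append(mask.shape[ax])
        else:
            lo.append(int(nz[ax].min()))
            hi.append(int(nz[ax].max()) + 1)
    return tuple(lo), tuple(hi)


def crop_pad_to_slices(
    vol: np.ndarray,
    plane: str,
    slice_size: int = 128,
    mask: np.ndarray | None = None,
) -> SliceStack:
    """In-plane crop to the brain bounding box, then pad to square slices.

    The crop box comes from `mask` (default: nonzero voxels of `vol`) over
    the two in-plane axes; every slice along the stacking axis is kept, so
    a 96^3 volume yields 96 slices per plane. Label volumes pass through
    unchanged in value (background pads).
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    vol = np.asarray(vol)
    stack_axis, inplane = PLANES[plane]
    support = mask if mask is not None else (vol != 0)
    lo, hi = _bbox(np.asarray(support), inplane)
    widths = tuple(h - l for l, h in zip(lo, hi))
    if any(w > slice_size for w in widths):
        raise ValueError(
            f"in-plane bounding box {widths} exceeds slice size {slice_size}; resample first"
        )
    sel = [slice(None)] * 3
    for ax, l, h in zip(inplane, lo, hi):
        sel[ax] = slice(l, h)
    cropped = vol[tuple(sel)]
    # reorder to (stack, horizontal, vertical)
    cropped = np.moveaxis(cropped, (stack_axis, *inplane), (0, 1, 2))
    pad_lo = tuple((slice_size - w) // 2 for w in widths)
    pads = [(0, 0)] + [
        (p, slice_size - w - p) for p, w in zip(pad_lo, widths)
    ]
    slices = np.pad(cropped, pads)
    is_labels = np.issubdtype(vol.dtype, np.integer)
    geom = SliceGeometry(
        plane=plane,
        orig_shape=tuple(vol.shape),
        crop_lo=lo,
        crop_hi=hi,
        pad_lo=pad_lo,
        slice_size=slice_size,
    )
    scheme = None
    if is_labels:
        scheme = 3 if int(vol.max()) <= 2 and plane == "sagittal" else 5
    return SliceStack(plane=plane, slices=slices, geometry=geom, label_scheme=scheme)


def reassemble_slices(stack: SliceStack) -> np.ndarray:
    """Invert crop_pad_to_slices: scalar volume on the original grid (zeros outside crop)."""
    g = stack.geometry
    stack_axis, inplane = PLANES[g.plane]
    w = tuple(h - l for l, h in zip(g.crop_lo, g.crop_hi))
    core = stack.slices[
        :, g.pad_lo[0] : g.pad_lo[0] + w[0], g.pad_lo[1] : g.pad_lo[1] + w[1]
    ]
    core = np.moveaxis(core, (0, 1, 2), (stack_axis, *inplane))
    out = np.zeros(g.orig_shape, dtype=stack.slices.dtype)
    sel = [slice(None)] * 3
    for ax, l, h in zip(inplane, g.crop_lo, g.crop_hi):
        sel[ax] = slice(l, h)
    out[tuple(sel)] = core
    return out


def remap_labels_for_plane(labels: np.ndarray, plane: str) -> np.ndarray:
    """Axial/coronal keep the 5-label scheme; sagittal collapses left/right."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 4:
        raise ValueError("labels must be in 0..4")
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    if plane != "sagittal":
        return labels.copy()
    return SAGITTAL_LABEL_MAP[labels]


def reassemble_probabilities(probs: np.ndarray, geometry: SliceGeometry) -> np.ndarray:
    """Per-slice softmax maps -> 4D probability volume (labels, x, y, z).

    Padded in-plane margins are dropped; voxels outside the crop box get a
    one-hot background so every voxel stays on the probability simplex.
    """
    probs = np.asarray(probs, dtype=np.float32)
    g = geometry
    stack_axis, inplane = PLANES[g.plane]
    n_expected = g.orig_shape[stack_axis]
    if probs.ndim != 4 or probs.shape[0] != n_expected or probs.shape[2:] != (
        g.slice_size,
        g.slice_size,
    ):
        raise ValueError(
            f"slice stack shape {probs.shape} inconsistent with geometry "
            f"(expected ({n_expected}, L, {g.slice_size}, {g.slice_size}))"
        )
    n_labels = probs.shape[1]
    w = tuple(h - l for l, h in zip(g.crop_lo, g.crop_hi))
    core = probs[
        :, :, g.pad_lo[0] : g.pad_lo[0] + w[0], g.pad_lo[1] : g.pad_lo[1] + w[1]
    ]
    # (stack, L, h, v) -> (L, x, y, z) on the crop box
    core = np.moveaxis(core, (1, 0, 2, 3), (0, 1 + stack_axis, 1 + inplane[0], 1 + inplane[1]))
    out = np.zeros((n_labels,) + tuple(g.orig_shape), dtype=np.float32)
    out[0] = 1.0  # background outside the crop box
    sel = [slice(None)] * 3
    for ax, l, h in zip(inplane, g.crop_lo, g.crop_hi):
        sel[ax] = slice(l, h)
    out[(slice(None),) + tuple(sel)] = core
    return out


def condition_case(intensity: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Full intensity conditioning: mask multiply then in-mask z-scoring."""
    return zscore_normalize(apply_brain_mask(intensity, mask), mask=mask)
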