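"""Test-time augmentation and multi-view aggregation.

Each plane network predicts softmax maps for flipped copies of its slices
(original, horizontal, vertical, horizontal+vertical). Flips are undone on
the outputs before summing; a flip along the left-right in-plane axis of an
axial or coronal slice additionally swaps the left/right label channels
(1 <-> 2 and 3 <-> 4). Sagittal slices carry no left-right axis, use the
collapsed 3-label scheme, and contribute 3 augmented predictions (the
combined flip is dropped to keep the total at 11).

Per-plane summed probability volumes are combined by voxelwise summation
followed by argmax over labels; the sagittal 3-label volume is first
broadcast to 5 labels by adding its inner/plate probabilities to both the
left and the right channel, exactly as the aggregation equations prescribe
(no renormalization anywhere - argmax is scale-free per plane but the
duplication of the sagittal channels is intentional). The MVT path
aggregates 11 predictions (4 axial + 4 coronal + 3 sagittal), the
multi-view path 3, the single-plane paths 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .network import UNet, predict_stack
from .preprocess import PLANES, SliceStack, crop_pad_to_slices, reassemble_probabilities

FULL_FLIPS: tuple = ((), ("horizontal",), ("vertical",), ("horizontal", "vertical"))
SAGITTAL_FLIPS: tuple = ((), ("horizontal",), ("vertical",))

#: aggregation mode -> planes used and whether TTA is applied
MODES: dict = {
    "axi": (("axial",), False),
    "cor": (("coronal",), False),
    "tta-axi": (("axial",), True),
    "tta-cor": (("coronal",), True),
    "multiview": (("axial", "coronal", "sagittal"), False),
    "mvt": (("axial", "coronal", "sagittal"), True),
}


@dataclass(frozen=True)
class FlipTransform:
    """A spatial flip of a slice plus the label bookkeeping it implies."""

    plane: str
    axes: tuple = ()

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if any(a not in ("horizontal", "vertical") for a in self.axes):
            raise ValueError(f"unknown flip axes {self.axes!r}")

    @property
    def swaps_lr(self) -> bool:
        """True iff the flip mirrors the left-right axis of an axial/coronal slice."""
        return "horizontal" in self.axes and self.plane in ("axial", "coronal")

    def apply_spatial(self, maps: np.ndarray) -> np.ndarray:
        """Flip the last two axes (horizontal, vertical) of a slice array."""
        flips = []
        if "horizontal" in self.axes:
            flips.append(maps.ndim - 2)
        if "vertical" in self.axes:
            flips.append(maps.ndim - 1)
        return np.flip(maps, axis=tuple(flips)) if flips else maps


def swap_lr_channels(maps: np.ndarray) -> np.ndarray:
    """Exchange left/right label channels (1<->2, 3<->4) of 5-label maps."""
    if maps.shape[1] != 5:
        raise ValueError("left-right label swap requires 5-label maps")
    return maps[:, [0, 2, 1, 4, 3]]


def tta_transform_inverse(maps: np.ndarray, flip: FlipTransform) -> np.ndarray:
    """Undo a flip on predicted maps, swapping left/right labels if needed.

    maps: (n_slices, n_labels, H, V) softmax outputs predicted on flipped
    input slices. Flips are involutions, so the inverse is the flip itself.
    """
    out = flip.apply_spatial(maps)
    if flip.swaps_lr:
        out = swap_lr_channels(out)
    return out


@dataclass
class PlaneProbability:
    """Summed probability volume of one plane and how many predictions built it."""

    plane: str
    prob: np.ndarray  # (n_labels, x, y, z)
    n_predictions: int


def flips_for_plane(plane: str, tta: bool) -> tuple:
    if not tta:
        return ((),)
    return SAGITTAL_FLIPS if plane == "sagittal" else FULL_FLIPS


def _predict(model, slices: np.ndarray) -> np.ndarray:
    if isinstance(model, UNet):
        return predict_stack(model, slices)
    return np.asarray(model(slices), dtype=np.float32)


def tta_sum(model, stack: SliceStack, flips: Sequence[tuple] | None = None) -> PlaneProbability:
    """Predict every flip-augmented copy of a slice stack and sum the outputs.

    Each augmented stack is predicted, inverse-transformed (undoing the
    spatial flip and swapping left/right channels where the flip mirrored
    the left-right axis) and accumulated. The per-voxel channel sum of the
    result equals the number of predictions, since each softmax map sums
    to one.
    """
    if flips is None:
        flips = flips_for_plane(stack.plane, tta=True)
    flips = [f if isinstance(f, FlipTransform) else FlipTransform(stack.plane, tuple(f)) for f in flips]
    if not flips:
        raise ValueError("flip list must not be empty")
    total = None
    for flip in flips:
        maps = _predict(model, flip.apply_spatial(stack.slices))
        maps = tta_transform_inverse(maps, flip)
        total = maps if total is None else total + maps
    vol = reassemble_probabilities(total, stack.geometry)
    # outside-crop voxels got a single one-hot background from reassembly;
    # scale them to n votes so the per-voxel channel sum is n everywhere
    outside = (vol[0] == 1.0) & (vol[1:].sum(axis=0) == 0.0)
    vol[0][outside] = float(len(flips))
    return PlaneProbability(plane=stack.plane, prob=vol, n_predictions=len(flips))


def broadcast_sagittal(p_sag: PlaneProbability) -> np.ndarray:
    """Lift a 3-label sagittal volume to the 5-label scheme.

    The inner-volume probability is added to both the left and right inner
    channels, and likewise for the plate channel; the duplication is part
    of the aggregation rule.
    """
    if p_sag.prob.shape[0] != 3:
        raise ValueError("broadcast_sagittal expects a 3-label volume")
    bg, inner, plate = p_sag.prob
    return np.stack([bg, inner, inner, plate, plate]).astype(np.float32)


def aggregate(prob_volumes: Iterable[np.ndarray]) -> np.ndarray:
    """Sum 5-label probability volumes voxelwise and take the argmax label.

    Ties break toward the lowest label index (background wins), which is
    numpy's argmax convention.
    """
    vols = list(prob_volumes)
    if not vols:
        raise ValueError("nothing to aggregate")
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape:
            raise ValueError(f"grid mismatch: {v.shape} vs {shape}")
    return np.argmax(sum(vols), axis=0).astype(np.uint8)


def predict_volume(
    models: dict,
    intensity: np.ndarray,
    mode: str = "mvt",
    slice_size: int = 128,
    mask: np.ndarray | None = None,
    return_prob: bool = False,
):
    """Segment a conditioned intensity volume with the requested aggregation mode.

    models: {'axial': ..., 'coronal': ..., 'sagittal': ...}; each entry is a
    trained UNet or any callable mapping (n, S, S) slices to (n, L, S, S)
    softmax maps. Returns the label volume (and, optionally, the summed
    5-label probability volume and the per-plane prediction counts).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(MODES)}")
    planes, tta = MODES[mode]
    missing = [p for p in planes if p not in models or models[p] is None]
    if missing:
        raise ValueError(f"missing plane model(s): {missing}")
    plane_sums, counts = [], {}
    for plane in planes:
        stack = crop_pad_to_slices(intensity, plane, slice_size=slice_size, mask=mask)
        pp = tta_sum(models[plane], stack, flips_for_plane(plane, tta))
        counts[plane] = pp.n_predictions
        if pp.prob.shape[0] == 3:
            pp = PlaneProbability(plane, broadcast_sagittal(pp), pp.n_predictions)
        elif pp.prob.shape[0] != 5:
            raise ValueError(f"{plane} model produced {pp.prob.shape[0]} labels")
        plane_sums.append(pp.prob)
    labels = aggregate(plane_sums)
    if return_prob:
        return labels, sum(plane_sums), counts
    return labels
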