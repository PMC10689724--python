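"""Whole-volume inference: tri-planar prediction, fusion and thresholding.

Every slice of a normalized volume is resized to the network input
resolution and predicted independently; the per-slice probability maps
are inverse-resized to their native shape and restacked to a 3D volume.
Doing this for the axial, coronal and sagittal planes yields three
probability volumes that are averaged voxelwise and finally thresholded
to one binary lesion mask (thresholding last, in probability space).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataprep import (
    LesionMask,
    MultiModalVolume,
    PLANES,
    restack_slices,
    slice_volume,
)
from .metrics import voxel_metrics
from .nn import Tensor
from .nn import no_grad as nn_no_grad


@dataclasses.dataclass
class ProbabilityVolume:
    """3D lesion-probability grid with provenance."""

    data: np.ndarray
    plane: str  # "axial" | "coronal" | "sagittal" | "fused"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError("probability volume must be 3D")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.data = arr

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass(frozen=True)
class ThresholdPolicy:
    """Fixed cut or DSC-maximizing grid search on validation pairs."""

    mode: str = "fixed"  # fixed | dsc_max
    value: float = 0.5
    grid_step: float = 0.05
    scale: float = 1.0  # post-hoc multiplier (e.g. +10% after fine-tuning)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "dsc_max"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not 0.0 < self.value < 1.0:
            raise ValueError("fixed threshold must lie in (0, 1)")
        if not 0.0 < self.grid_step <= 0.1:
            raise ValueError("grid step must divide (0,1) into >= 10 candidates")


def predict_plane(model, vol: MultiModalVolume, plane: str,
                  batch_size: int = 50) -> ProbabilityVolume:
    """Predict every slice along one plane and restack to 3D."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    records = slice_volume(vol, mask=None, plane=plane)
    mods = vol.modalities
    prob_slices = []
    if hasattr(model, "eval"):
        model.eval()
    with nn_no_grad():
        for ofs in range(0, len(records), batch_size):
            chunk = records[ofs : ofs + batch_size]
            xs = [
                Tensor(np.stack([r.images[m] for r in chunk])[:, None])
                for m in mods
            ]
            pred = model(xs)
            arr = pred.data if hasattr(pred, "data") else np.asarray(pred)
            prob_slices.extend(np.clip(arr[:, 0], 0.0, 1.0))
    out = restack_slices(prob_slices, plane, vol.shape, order=1)
    return ProbabilityVolume(np.clip(out, 0.0, 1.0), plane)


def fuse(axial: ProbabilityVolume, coronal: ProbabilityVolume,
         sagittal: ProbabilityVolume) -> ProbabilityVolume:
    """Voxelwise arithmetic mean of the three per-plane volumes."""
    vols = (axial, coronal, sagittal)
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch between plane volumes: {shapes}")
    mean = np.mean([v.data for v in vols], axis=0)
    return ProbabilityVolume(mean.astype(np.float32), "fused")


def _threshold_grid(step: float) -> np.ndarray:
    return np.arange(step, 1.0 - step / 2, step)


def binarize(prob: ProbabilityVolume, policy: ThresholdPolicy = ThresholdPolicy(),
             validation_pairs=None) -> LesionMask:
    """Threshold a probability volume to a binary mask.

    fixed mode: mask = prob >= value (ties count as lesion).
    dsc_max mode: the threshold is chosen by a grid search over
    ``validation_pairs`` — a sequence of (ProbabilityVolume, LesionMask)
    — maximizing the mean DSC, then applied to ``prob``.  ``scale``
    multiplies the chosen threshold before application.
    """
    if policy.mode == "fixed":
        t = policy.value
    else:
        if not validation_pairs:
            raise ValueError("dsc_max mode requires validation pairs")
        t = find_dsc_max_threshold(validation_pairs, policy.grid_step)
    t = min(max(t * policy.scale, 0.0), 1.0)
    return LesionMask((prob.data >= t).astype(np.uint8))


def find_dsc_max_threshold(validation_pairs, grid_step: float = 0.05) -> float:
    """Grid-search the cut maximizing mean DSC over validation pairs."""
    best_t, best_d = 0.5, -np.inf
    for t in _threshold_grid(grid_step):
        ds = []
        for pv, gt in validation_pairs:
            pred = (pv.data >= t).astype(np.uint8)
            d = voxel_metrics(pred, gt.data)[0]
            if not np.isnan(d):
                ds.append(d)
        mean_d = float(np.mean(ds)) if ds else -np.inf
        if mean_d > best_d:
            best_d, best_t = mean_d, float(t)
    return best_t


def predict_volume(model, vol: MultiModalVolume,
                   policy: ThresholdPolicy = ThresholdPolicy(),
                   validation_pairs=None,
                   batch_size: int = 50):
    """Full tri-planar inference; returns (fused probability, binary mask)."""
    per_plane = [predict_plane(model, vol, p, batch_size) for p in PLANES]
    fused = fuse(*per_plane)
    mask = binarize(fused, policy, validation_pairs)
    return fused, mask
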