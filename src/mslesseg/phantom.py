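"""Synthetic multi-modal brain phantoms with known lesion masks.

The generator emulates the salient properties of skull-stripped,
co-registered MS study data: three intensity contrasts (FLAIR, T1w, T2w)
on a shared ~1 mm isotropic grid, focal lesions that are hyperintense on
FLAIR and T2w, an optional subset of chronic "black hole" lesions that
are hypointense on T1w, and heavy foreground/background class imbalance.
It also generates synthetic validation-loss traces used to exercise the
checkpoint-selection algorithm.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from .dataprep import LesionMask, MultiModalVolume

MODALITIES = ("FLAIR", "T1w", "T2w")

# Mean tissue intensities (arbitrary units) per modality.  Chosen so that
# lesions are clearly hyperintense on FLAIR/T2w, black holes hypointense
# on T1w, and normal-appearing tissue sits well above the zero background.
TISSUE_MEAN = {"FLAIR": 0.40, "T1w": 0.60, "T2w": 0.45}
LESION_MEAN = {"FLAIR": 0.90, "T1w": 0.65, "T2w": 0.85}
BLACK_HOLE_T1_MEAN = 0.20

# Brain = centred ellipsoid covering ~70% of each grid axis.
BRAIN_AXIS_FRACTION = 0.70


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed within the retry budget."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic multi-modal volume.

    Parameters
    ----------
    grid_shape : tuple of int
        Voxel grid, each axis >= 32 (nominally 1 mm isotropic voxels).
    n_lesions : int
        Number of ellipsoidal lesions to draw.
    lesion_radius_range : (float, float)
        Uniform sampling range for ellipsoid semi-axes, in voxels.
    black_hole_fraction : float
        Fraction of lesions rendered hypointense on T1w.
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise.
    seed : int
        Seed for all randomness in the generator.
    non_overlapping : bool
        If true, lesions are rejection-sampled so their bounding
        ellipsoids do not touch (useful when a test needs an exact
        connected-component count).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_lesions: int = 8
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)
    black_hole_fraction: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0
    non_overlapping: bool = False

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 32 for s in self.grid_shape):
            raise ValueError("grid_shape must be three integers, each >= 32")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        if not 0.0 <= self.black_hole_fraction <= 1.0:
            raise ValueError("black_hole_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.n_lesions < 0:
            raise ValueError("noise_sd and n_lesions must be non-negative")


@dataclasses.dataclass(frozen=True)
class LossHistorySpec:
    """Recipe for a synthetic per-epoch validation-loss trace."""

    n_epochs: int = 300
    trend: str = "decreasing"  # decreasing | plateau | noisy-spike
    noise_sd: float = 0.0
    checkpoint_stride: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1 or self.checkpoint_stride < 1:
            raise ValueError("n_epochs and checkpoint_stride must be positive")
        if self.trend not in ("decreasing", "plateau", "noisy-spike"):
            raise ValueError(f"unknown trend {self.trend!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    semi = [BRAIN_AXIS_FRACTION * s / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def _ellipsoid(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return r2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[MultiModalVolume, LesionMask]:
    """Draw a three-modality phantom volume and its binary lesion mask.

    Lesions are axis-aligned ellipsoids placed uniformly inside the brain
    ellipsoid (each lesion's bounding box fully inside the brain).  The
    black-hole subset is the first ``round(black_hole_fraction*n)`` lesions
    in placement order.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    brain = _brain_mask(shape)
    mask = np.zeros(shape, dtype=np.uint8)
    lesions: list[np.ndarray] = []
    placed_params: list[tuple[np.ndarray, np.ndarray]] = []

    n_black = int(round(spec.black_hole_fraction * spec.n_lesions))
    centre = np.array([(s - 1) / 2.0 for s in shape])
    brain_semi = np.array([BRAIN_AXIS_FRACTION * s / 2.0 for s in shape])

    for idx in range(spec.n_lesions):
        for _attempt in range(200):
            radii = rng.uniform(*spec.lesion_radius_range, size=3)
            # keep the lesion's bounding box inside the brain ellipsoid
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad_frac = rng.uniform(0, 1) ** (1 / 3)
            margin = (radii + 1.0) / brain_semi
            scale = max(0.0, 1.0 - float(np.max(margin)))
            pos = centre + u * rad_frac * scale * brain_semi
            les = _ellipsoid(shape, pos, radii)
            if not les.any() or not les[brain].any() or (les & ~brain).any():
                continue
            if spec.non_overlapping and any(
                (les & prev).any() for prev in lesions
            ):
                continue
            if spec.non_overlapping and any(
                np.all(np.abs(pos - p) <= (radii + r + 1.5))
                for p, r in placed_params
            ):
                # bounding boxes touch: components could merge after voxelization
                continue
            lesions.append(les)
            placed_params.append((pos, radii))
            mask |= les.astype(np.uint8)
            break
        else:
            raise LesionPlacementError(
                f"could not place lesion {idx} after 200 attempts"
            )

    data = {}
    for mod in MODALITIES:
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain] = TISSUE_MEAN[mod]
        for i, les in enumerate(lesions):
            if mod == "T1w" and i < n_black:
                vol[les] = BLACK_HOLE_T1_MEAN
            else:
                vol[les] = LESION_MEAN[mod]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
            vol[~brain] = 0.0
        data[mod] = vol.astype(np.float32)

    volume = MultiModalVolume(data, spacing=(1.0, 1.0, 1.0))
    return volume, LesionMask(mask)


def make_loss_history(spec: LossHistorySpec):
    """Generate a synthetic validation-loss history with checkpoint flags.

    ``decreasing``: exponential decay with strictly shrinking decrements.
    ``plateau``: initial decay that flattens out at a floor.
    ``noisy-spike``: a plateau with occasional sharp low-loss spikes, the
    regime the variance-window selection rule is designed to avoid.

    Checkpoint flags mirror the trainer's dual policy: every
    ``checkpoint_stride``-th epoch (1-based) and every running-best epoch.
    """
    from .trainer import LossHistory  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_epochs
    t = np.arange(n, dtype=np.float64)
    if spec.trend == "decreasing":
        base = 0.1 + 0.9 * np.exp(-t / max(n / 4.0, 1.0))
    elif spec.trend == "plateau":
        base = 0.2 + 0.8 * np.exp(-t / max(n / 20.0, 1.0))
    else:  # noisy-spike
        base = np.full(n, 0.3)
        n_spikes = max(1, n // 60)
        idx = rng.choice(np.arange(n // 4, n), size=n_spikes, replace=False)
        base[idx] -= rng.uniform(0.1, 0.25, size=n_spikes)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=n)
    losses = np.maximum(base, 1e-4)

    flags = np.zeros(n, dtype=bool)
    best = np.inf
    best_epoch = 0
    for e in range(n):
        if (e + 1) % spec.checkpoint_stride == 0:
            flags[e] = True
        if losses[e] < best:
            best = losses[e]
            best_epoch = e
            flags[e] = True
    return LossHistory(
        val_loss=losses, checkpoint_saved=flags, best_epoch=best_epoch
    )


def write_phantom_nifti(
    volume: MultiModalVolume,
    mask: LesionMask,
    out_dir: str | pathlib.Path,
    spec: PhantomSpec | None = None,
) -> dict[str, str]:
    """Write one NIfTI file per modality plus the mask and a JSON sidecar."""
    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    paths = {}
    for mod, arr in volume.data.items():
        p = out / f"{mod}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), p)
        paths[mod] = str(p)
    p = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), p)
    paths["mask"] = str(p)
    if spec is not None:
        sidecar = out / "phantom_spec.json"
        sidecar.write_text(json.dumps(dataclasses.asdict(spec), indent=2))
        paths["spec"] = str(sidecar)
    return paths
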