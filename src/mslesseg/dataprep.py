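"""Volume containers and 2D slice preparation.

3D multi-modal volumes are normalized per modality, sliced along the
axial, coronal and sagittal planes, resized to the network's 256x256
input resolution, filtered by the training-slice selection rule (all
lesion-bearing slices plus every 30th empty slice), and augmented.
"""

from __future__ import annotations

import dataclasses
import pathlib
from collections.abc import Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

PLANES = ("axial", "coronal", "sagittal")
#: axis sliced over for each plane, for volumes indexed (x, y, z)
PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}
TARGET_SHAPE = (256, 256)
DEFAULT_EMPTY_STRIDE = 30


class NormalizationError(ValueError):
    """Raised for degenerate (constant-valued) modalities."""


@dataclasses.dataclass
class MultiModalVolume:
    """Co-registered 3D intensity grids, one per modality.

    ``data`` maps modality label ("FLAIR", "T1w", "T2w") to a 3D array;
    all arrays must share one shape.  ``spacing`` is mm per axis.
    """

    data: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("at least one modality is required")
        shapes = {m: a.shape for m, a in self.data.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"modality grids disagree in shape: {shapes}")
        for m, a in self.data.items():
            if a.ndim != 3:
                raise ValueError(f"modality {m} is not a 3D grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.data.values())).shape

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.data.keys())


@dataclasses.dataclass
class LesionMask:
    """Binary 3D lesion mask aligned with a MultiModalVolume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3D")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class SliceRecord:
    """One multi-modality 2D sample at the network input resolution."""

    images: dict[str, np.ndarray]  # modality -> (256, 256) float image
    label: np.ndarray | None  # (256, 256) binary, or None at inference
    plane: str
    slice_index: int
    source_shape: tuple[int, int]  # native (rows, cols) before resize

    @property
    def has_lesion(self) -> bool:
        return self.label is not None and bool(self.label.any())


def normalize_intensity(vol: MultiModalVolume) -> MultiModalVolume:
    """Min-max rescale every modality to [0, 1] (order-preserving affine)."""
    out = {}
    for mod, arr in vol.data.items():
        lo = float(arr.min())
        hi = float(arr.max())
        if hi == lo:
            raise NormalizationError(f"modality {mod} is constant-valued")
        out[mod] = ((arr - lo) / (hi - lo)).astype(np.float32)
    return MultiModalVolume(out, spacing=vol.spacing)


def _extract_slice(arr: np.ndarray, plane: str, idx: int) -> np.ndarray:
    ax = PLANE_AXIS[plane]
    return np.take(arr, idx, axis=ax)


def resize_image(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize for intensity images (float output)."""
    if img.shape == tuple(shape):
        return img.astype(np.float32)
    return resize(
        img.astype(np.float64), shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(np.float32)


def resize_label(lab: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize for labels; preserves binarity exactly."""
    if lab.shape == tuple(shape):
        return lab.astype(np.uint8)
    return resize(
        lab.astype(np.float64), shape, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(np.uint8)


def slice_volume(
    vol: MultiModalVolume,
    mask: LesionMask | None = None,
    plane: str = "axial",
    target_shape: tuple[int, int] = TARGET_SHAPE,
) -> list[SliceRecord]:
    """Slice a normalized volume along one plane into resized records."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    if mask is not None and mask.shape != vol.shape:
        raise ValueError("mask shape does not match volume shape")
    ax = PLANE_AXIS[plane]
    n = vol.shape[ax]
    records = []
    for idx in range(n):
        images = {}
        src_shape = None
        for mod, arr in vol.data.items():
            sl = _extract_slice(arr, plane, idx)
            src_shape = sl.shape
            images[mod] = resize_image(sl, target_shape)
        label = None
        if mask is not None:
            label = resize_label(
                _extract_slice(mask.data, plane, idx), target_shape
            )
        records.append(
            SliceRecord(images, label, plane, idx, tuple(src_shape))
        )
    return records


def restack_slices(
    slices: Sequence[np.ndarray],
    plane: str,
    volume_shape: tuple[int, int, int],
    order: int = 1,
) -> np.ndarray:
    """Inverse of :func:`slice_volume` for per-slice 2D maps.

    Each 2D map is resized back to its native slice shape (bilinear for
    probabilities, ``order=0`` for labels) and restacked along the
    plane's axis to a 3D array of ``volume_shape``.
    """
    ax = PLANE_AXIS[plane]
    native = tuple(s for i, s in enumerate(volume_shape) if i != ax)
    out = np.empty(volume_shape, dtype=np.float32)
    indexer = [slice(None)] * 3
    for idx, sl in enumerate(slices):
        if order == 0:
            back = resize_label(np.asarray(sl), native)
        else:
            back = resize_image(np.asarray(sl), native)
        indexer[ax] = idx
        out[tuple(indexer)] = back
    return out


def select_training_slices(
    records: Sequence[SliceRecord],
    empty_stride: int = DEFAULT_EMPTY_STRIDE,
) -> list[SliceRecord]:
    """Keep all lesion-bearing slices plus every ``empty_stride``-th empty one.

    The stride counts 1-based within the ordered subsequence of slices
    whose label is all zero; the output preserves input order.
    """
    if empty_stride < 1:
        raise ValueError("empty_stride must be positive")
    kept = []
    n_empty = 0
    for rec in records:
        if rec.label is None:
            raise ValueError("select_training_slices requires labeled records")
        if rec.has_lesion:
            kept.append(rec)
        else:
            n_empty += 1
            if n_empty % empty_stride == 0:
                kept.append(rec)
    return kept


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Augmentation ranges; all transforms are sampled uniformly."""

    rotation_deg: float = 15.0
    shift_frac: float = 0.10
    zoom_frac: float = 0.10
    brightness_frac: float = 0.20
    flip_horizontal: bool = True
    flip_vertical: bool = True


def augment(
    rec: SliceRecord,
    rng: np.random.Generator,
    cfg: AugmentConfig = AugmentConfig(),
) -> SliceRecord:
    """Random rotation/flip/shift/zoom/brightness of one training record.

    One geometric transform is sampled and applied identically to every
    modality image (bilinear) and to the label (nearest-neighbour, so it
    stays binary).  Brightness scaling applies to the images only.
    """
    if rec.label is None:
        raise ValueError("augment expects a training record with a label")
    h, w = next(iter(rec.images.values())).shape

    angle = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    tx = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * w
    ty = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * h
    zoom = 1.0 + rng.uniform(-cfg.zoom_frac, cfg.zoom_frac)
    flip_h = cfg.flip_horizontal and rng.random() < 0.5
    flip_v = cfg.flip_vertical and rng.random() < 0.5
    bright = 1.0 + rng.uniform(-cfg.brightness_frac, cfg.brightness_frac)

    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        AffineTransform(translation=-centre)
        + AffineTransform(rotation=angle, scale=(zoom, zoom))
        + AffineTransform(translation=centre)
        + AffineTransform(translation=(tx, ty))
    )

    def geom(img: np.ndarray, order: int) -> np.ndarray:
        out = img
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        if (
            cfg.rotation_deg == 0
            and cfg.shift_frac == 0
            and cfg.zoom_frac == 0
        ):
            return np.ascontiguousarray(out)
        return warp(
            out.astype(np.float64), tf.inverse, order=order, mode="constant",
            cval=0.0, preserve_range=True,
        )

    images = {
        mod: np.clip(geom(img, order=1) * bright, 0.0, None).astype(np.float32)
        for mod, img in rec.images.items()
    }
    label = (geom(rec.label, order=0) > 0.5).astype(np.uint8)
    return SliceRecord(images, label, rec.plane, rec.slice_index,
                       rec.source_shape)


def load_nifti_volume(
    paths: dict[str, str | pathlib.Path],
    mask_path: str | pathlib.Path | None = None,
) -> tuple[MultiModalVolume, LesionMask | None]:
    """Read one NIfTI file per modality (plus optional mask)."""
    import nibabel as nib

    data = {}
    spacing = (1.0, 1.0, 1.0)
    for mod, p in paths.items():
        img = nib.load(str(p))
        data[mod] = np.asarray(img.dataobj, dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        arr = np.asarray(nib.load(str(mask_path)).dataobj)
        mask = LesionMask((arr > 0.5).astype(np.uint8))
    return MultiModalVolume(data, spacing=spacing), mask


def export_png_slices(
    records: Sequence[SliceRecord],
    out_dir: str | pathlib.Path,
) -> list[pathlib.Path]:
    """Lossy 8-bit export mirroring a per-plane/per-modality layout."""
    import imageio.v3 as iio

    out = pathlib.Path(out_dir)
    written = []
    for rec in records:
        for mod, img in rec.images.items():
            d = out / rec.plane / mod
            d.mkdir(parents=True, exist_ok=True)
            p = d / f"slice_{rec.slice_index:04d}.png"
            iio.imwrite(p, np.clip(img * 255, 0, 255).astype(np.uint8))
            written.append(p)
        if rec.label is not None:
            d = out / rec.plane / "label"
            d.mkdir(parents=True, exist_ok=True)
            p = d / f"slice_{rec.slice_index:04d}.png"
            iio.imwrite(p, (rec.label * 255).astype(np.uint8))
            written.append(p)
    return written
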