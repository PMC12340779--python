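"""CT preprocessing: isotropic resampling, nodule cropping, HU normalization,
nine-plane 2.5D view extraction, and train-time volumetric augmentation.

The pipeline mirrors standard practice for nodule-level models: resample the
scan to 1 mm isotropic spacing, place a 50 x 50 x 50 mm box around the nodule
centroid (padding with air where the box leaves the scan), clip Hounsfield
units to [-1000, 500] and map them linearly to [0, 1], then slice the cube
along nine symmetry planes through the centroid.  Each plane is resized to the
encoder's input size, replicated to three channels, and standardized with the
image-text pretraining constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "HU_MIN", "HU_MAX", "CROP_SIZE_MM", "PAD_HU", "CLIP_PIXEL_MEAN", "CLIP_PIXEL_STD",
    "CTVolume", "NoduleLocus", "NoduleCrop", "ViewStack", "AugmentationPolicy",
    "hu_to_unit", "resample_isotropic", "crop_and_normalize", "nine_plane_frames",
    "extract_nine_views", "to_view_stack", "augment_crop", "load_nifti",
    "load_dicom_series", "load_volume", "read_manifest",
]

HU_MIN = -1000.0
HU_MAX = 500.0
CROP_SIZE_MM = 50
PAD_HU = -1000.0  # air
_CROP_CENTER = CROP_SIZE_MM // 2  # voxel index of the centroid within the crop

# published preprocessing constants of the pretrained image-text model family
CLIP_PIXEL_MEAN = (0.48145466, 0.4578275, 0.40821073)
CLIP_PIXEL_STD = (0.26862954, 0.26130258, 0.27577711)


# --------------------------------------------------------------------- types
@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units with world geometry.

    World coordinates follow ``world = origin + index * spacing`` with voxel
    indices ordered like the world axes (``axis_order`` tag, default "xyz").
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_order: str = "xyz"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("volume must be a non-empty 3D grid")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive on all three axes")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.array(self.voxels.shape) - 1) * self.spacing

    def world_to_index(self, world_mm) -> np.ndarray:
        return (np.asarray(world_mm, dtype=np.float64) - self.origin) / self.spacing


@dataclass
class NoduleLocus:
    patient_id: str
    nodule_id: str
    centroid_mm: np.ndarray
    label: int
    cohort: str = ""

    def __post_init__(self):
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=np.float64)
        if int(self.label) not in (0, 1):
            raise ValueError("label must be binary")
        self.label = int(self.label)


@dataclass
class NoduleCrop:
    """A 50^3 cube at 1 mm isotropic spacing with intensities in [0, 1]."""

    cube: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cube = np.asarray(self.cube, dtype=np.float32)
        if self.cube.shape != (CROP_SIZE_MM,) * 3:
            raise ValueError(f"crop must be {CROP_SIZE_MM}^3")
        if self.cube.min() < -1e-6 or self.cube.max() > 1 + 1e-6:
            raise ValueError("crop intensities must lie in [0, 1]")


@dataclass
class ViewStack:
    """Nine standardized 224 x 224 (or encoder-sized) 3-channel views plus the
    orthonormal plane frame (normal and two in-plane axes) of each view."""

    views: np.ndarray  # (9, 3, S, S)
    frames: list

    def __post_init__(self):
        self.views = np.asarray(self.views, dtype=np.float32)
        if self.views.shape[0] != 9 or self.views.shape[1] != 3:
            raise ValueError("a view stack holds exactly 9 three-channel views")


@dataclass
class AugmentationPolicy:
    """Train-time augmentation magnitudes (all applied to the 3D crop)."""

    jitter_max_mm: float = 5.0
    flip_prob: float = 0.5
    max_rotation_deg: float = 10.0
    noise_mean: float = 0.0
    noise_sd: float = 0.02
    log_gamma_range: tuple[float, float] = (-0.02, 0.02)
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.jitter_max_mm < 0 or self.max_rotation_deg < 0 or self.noise_sd < 0:
            raise ValueError("augmentation magnitudes must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(jitter_max_mm=0.0, flip_prob=0.0, max_rotation_deg=0.0,
                   noise_sd=0.0, log_gamma_range=(0.0, 0.0))


# ---------------------------------------------------------------- operations
def hu_to_unit(x):
    """Clip HU to [-1000, 500] and map linearly onto [0, 1]."""
    return (np.clip(x, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN)


def resample_isotropic(vol: CTVolume, target_spacing_mm: float = 1.0) -> CTVolume:
    """Trilinear resampling onto an isotropic grid sharing the volume origin.

    Because the new grid is anchored at the origin, the world coordinate of
    any landmark is preserved exactly up to interpolation.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    shape = np.array(vol.voxels.shape)
    new_shape = np.floor((shape - 1) * vol.spacing / target_spacing_mm).astype(int) + 1
    if np.allclose(vol.spacing, target_spacing_mm) and np.all(new_shape == shape):
        return CTVolume(vol.voxels.copy(), np.full(3, float(target_spacing_mm)),
                        vol.origin.copy(), vol.axis_order)
    axes = [np.arange(n) * target_spacing_mm / s for n, s in zip(new_shape, vol.spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.voxels, np.stack(coords), order=1,
                                  mode="nearest")
    return CTVolume(out.astype(np.float32), np.full(3, float(target_spacing_mm)),
                    vol.origin.copy(), vol.axis_order)


def crop_and_normalize(vol: CTVolume, centroid_mm) -> NoduleCrop:
    """Extract the 50^3 1 mm cube around the centroid and normalize HU to [0,1].

    Out-of-volume samples are filled with -1000 HU (air) before normalization,
    so padded voxels are exactly 0 afterwards.
    """
    if not np.allclose(vol.spacing, 1.0, atol=1e-3):
        raise ValueError("crop_and_normalize expects a 1 mm isotropic volume")
    centroid_mm = np.asarray(centroid_mm, dtype=np.float64)
    idx = vol.world_to_index(centroid_mm)
    hi = np.array(vol.voxels.shape) - 1
    if np.any(idx < -_CROP_CENTER) or np.any(idx > hi + _CROP_CENTER):
        raise ValueError("centroid lies more than 25 mm outside the volume; "
                         "the crop would contain no data")
    c = np.round(idx).astype(int)
    start = c - _CROP_CENTER
    cube = np.full((CROP_SIZE_MM,) * 3, PAD_HU, dtype=np.float32)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + CROP_SIZE_MM, vol.voxels.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        cube[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            vol.voxels[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return NoduleCrop(hu_to_unit(cube),
                      provenance={"centroid_mm": centroid_mm.tolist(),
                                  "center_index": c.tolist()})


_PLANE_NORMALS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
], dtype=np.float64)


def nine_plane_frames() -> list[dict]:
    """Orthonormal frames of the cube's nine symmetry planes.

    The first in-plane axis is the normalized projection of the lowest-index
    world axis not parallel to the plane normal; the second completes a
    right-handed frame.
    """
    frames = []
    for n in _PLANE_NORMALS:
        n_hat = n / np.linalg.norm(n)
        for k in range(3):
            axis = np.zeros(3)
            axis[k] = 1.0
            if abs(axis @ n_hat) < 1.0 - 1e-9:
                break
        e1 = axis - (axis @ n_hat) * n_hat
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n_hat, e1)
        frames.append({"normal": n_hat, "e1": e1, "e2": e2})
    return frames


def extract_nine_views(crop: NoduleCrop) -> tuple[np.ndarray, list[dict]]:
    """Sample the crop on 50 x 50 1-mm grids along the nine symmetry planes.

    Every plane passes through the centroid voxel (cube index 25 on each
    axis); samples falling outside the cube take the padding value 0.
    """
    frames = nine_plane_frames()
    offsets = np.arange(CROP_SIZE_MM, dtype=np.float64) - _CROP_CENTER
    center = np.full(3, float(_CROP_CENTER))
    views = np.empty((9, CROP_SIZE_MM, CROP_SIZE_MM), dtype=np.float32)
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")
    for i, fr in enumerate(frames):
        pts = (center[:, None, None]
               + fr["e1"][:, None, None] * uu[None]
               + fr["e2"][:, None, None] * vv[None])
        views[i] = ndimage.map_coordinates(crop.cube, pts, order=1,
                                           mode="constant", cval=0.0)
    return views, frames


def to_view_stack(planes: np.ndarray, frames: list | None = None,
                  out_size: int = 224,
                  mean: tuple = CLIP_PIXEL_MEAN,
                  std: tuple = CLIP_PIXEL_STD) -> ViewStack:
    """Resize each plane, replicate to 3 channels, standardize per channel."""
    planes = np.asarray(planes, dtype=np.float32)
    if planes.shape[0] != 9:
        raise ValueError("expected exactly 9 planes")
    if frames is None:
        frames = nine_plane_frames()
    out = np.empty((9, 3, out_size, out_size), dtype=np.float32)
    mean = np.asarray(mean, dtype=np.float32)[:, None, None]
    std = np.asarray(std, dtype=np.float32)[:, None, None]
    for i, plane in enumerate(planes):
        if plane.shape != (out_size, out_size):
            plane = _sk_resize(plane, (out_size, out_size), order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True)
        rgb = np.repeat(plane[None].astype(np.float32), 3, axis=0)
        out[i] = (rgb - mean) / std
    return ViewStack(out, frames)


def augment_crop(vol: CTVolume, centroid_mm, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> NoduleCrop:
    """Stochastic training crop: centroid jitter, axis flips, small rotation,
    Gaussian noise and a log-gamma contrast perturbation, in that order.

    A zero-magnitude policy reproduces :func:`crop_and_normalize` exactly.
    Noise and gamma operate on the normalized [0, 1] intensities, and the
    result is re-clipped to [0, 1].
    """
    centroid_mm = np.asarray(centroid_mm, dtype=np.float64)
    if policy.jitter_max_mm > 0:
        centroid_mm = centroid_mm + rng.uniform(-policy.jitter_max_mm,
                                                policy.jitter_max_mm, size=3)
    crop = crop_and_normalize(vol, centroid_mm)
    cube = crop.cube
    if policy.flip_prob > 0:
        for ax in range(3):
            if rng.random() < policy.flip_prob:
                cube = np.flip(cube, axis=ax)
    if policy.max_rotation_deg > 0:
        angle = rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg)
        plane = tuple(rng.choice(3, size=2, replace=False))
        cube = ndimage.rotate(cube, angle, axes=plane, reshape=False, order=1,
                              mode="constant", cval=0.0)
    if policy.noise_sd > 0:
        cube = cube + rng.normal(policy.noise_mean, policy.noise_sd, cube.shape)
    lo, hi = policy.log_gamma_range
    if hi > lo or lo != 0.0:
        gamma = float(np.exp(rng.uniform(lo, hi)))
        cube = np.clip(cube, 0.0, 1.0) ** gamma
    return NoduleCrop(np.clip(cube, 0.0, 1.0).astype(np.float32),
                      provenance=dict(crop.provenance, augmented=True))


# -------------------------------------------------------------------- readers
def load_nifti(path) -> CTVolume:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return CTVolume(data, spacing, origin, axis_order="xyz")


def load_dicom_series(directory) -> CTVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FileNotFoundError(f"no DICOM series found under {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK arrays are (z, y, x); reorder to match the world axis order
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32)
    return CTVolume(data, np.asarray(img.GetSpacing(), dtype=np.float64),
                    np.asarray(img.GetOrigin(), dtype=np.float64), axis_order="xyz")


def load_volume(path) -> CTVolume:
    p = Path(path)
    if p.is_dir():
        return load_dicom_series(p)
    return load_nifti(p)


MANIFEST_COLUMNS = ["patient_id", "nodule_id", "image_path", "x_mm", "y_mm", "z_mm", "label"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "nodule_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    return df
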