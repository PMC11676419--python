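"""MRI slice preparation pipeline.

Volume -> axial slices -> end-of-stack blank-slice trimming -> resize to the
network's working resolution (192 x 192) -> per-slice min-max normalisation
-> paired geometric augmentation -> seeded train/validation split.

NIfTI IO goes through nibabel; resampling and warps through scikit-image
(bilinear for images, nearest for masks so they stay binary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

try:  # nibabel is a hard dependency, guarded only for a clearer error
    import nibabel as nib
except ImportError as exc:  # pragma: no cover
    raise ImportError("strokeseg.preprocessing requires nibabel") from exc

from skimage.transform import AffineTransform, resize, rotate, warp

logger = logging.getLogger(__name__)

__all__ = [
    "Volume", "SlicePair", "SplitDataset",
    "load_volume", "save_volume", "extract_slices", "remove_blank_slices",
    "resize_slice", "normalize", "augment", "split", "preprocess_subject",
]

TARGET_SIZE = 192
MODALITIES = ("FLAIR", "DWI", "T1", "T2", "mask")


@dataclass
class Volume:
    """A single-modality scan, depth-major (slices, height, width)."""

    subject_id: str
    modality: str
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class SlicePair:
    """One 2D image slice in [0, 1] with its binary mask and provenance."""

    image: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    slice_index: int = -1
    augmentation: str = "none"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shapes differ: {self.image.shape} vs "
                f"{self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)

    @property
    def provenance(self) -> tuple:
        return (self.subject_id, self.slice_index, self.augmentation)


@dataclass
class SplitDataset:
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    seed: int = 0
    train_fraction: float = 0.8


# -- IO ---------------------------------------------------------------------

def load_volume(path, subject_id: str = "", modality: str = "DWI") -> Volume:
    """Read a NIfTI volume; axes are normalised to depth-major order
    (NIfTI stores x, y, z: the slice axis comes last on disk)."""
    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path!s}: {exc}") from exc
    if arr.ndim != 3:
        raise IOError(f"{path!s}: expected a 3D volume, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume(subject_id=subject_id or str(path), modality=modality,
                  data=np.ascontiguousarray(arr.T.astype(np.float32)),
                  spacing=tuple(float(z) for z in reversed(zooms)))


def save_volume(volume: Volume, path) -> None:
    """Write a depth-major volume back to NIfTI (x, y, z on disk)."""
    data = np.ascontiguousarray(volume.data.T)
    img = nib.Nifti1Image(data, affine=np.diag(
        list(reversed(volume.spacing)) + [1.0]))
    img.header.set_zooms(tuple(reversed(volume.spacing)))
    nib.save(img, str(path))


# -- slice pipeline ---------------------------------------------------------

def extract_slices(volume: Volume) -> list[np.ndarray]:
    """One 2D image per axial index, order preserved."""
    return [volume.data[k] for k in range(volume.n_slices)]


def _foreground_fraction(img: np.ndarray) -> float:
    m = float(img.max())
    if m <= 0:
        return 0.0
    return float(np.mean(img > 0.01 * m))


def remove_blank_slices(slices: list[np.ndarray], masks: list[np.ndarray],
                        fg_threshold: float = 0.02
                        ) -> tuple[list, list, list[int]]:
    """Drop information-poor slices from *both ends* of the stack.

    A slice is blank when fewer than ``fg_threshold`` of its pixels exceed
    1% of the slice maximum.  Interior blanks are never removed.  Returns the
    kept slices, masks and their original indices.
    """
    if len(slices) != len(masks):
        raise ValueError("slices and masks must be aligned")
    n = len(slices)
    blank = [_foreground_fraction(s) < fg_threshold for s in slices]
    lo = 0
    while lo < n and blank[lo]:
        lo += 1
    hi = n
    while hi > lo and blank[hi - 1]:
        hi -= 1
    if lo >= hi:
        logger.warning("all %d slices are blank; nothing kept", n)
        return [], [], []
    kept = list(range(lo, hi))
    return [slices[k] for k in kept], [masks[k] for k in kept], kept


def resize_slice(image: np.ndarray, target: int = TARGET_SIZE,
                 kind: str = "image") -> np.ndarray:
    """Resample to ``target x target``: bilinear for images, nearest for
    masks (so masks stay exactly binary)."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {arr.shape}")
    if kind == "mask":
        out = resize(arr.astype(np.float32), (target, target), order=0,
                     preserve_range=True, anti_aliasing=False)
        return (out > 0.5).astype(np.uint8)
    out = resize(arr.astype(np.float32), (target, target), order=1,
                 preserve_range=True, anti_aliasing=False)
    return out.astype(np.float32)


def normalize(image: np.ndarray) -> np.ndarray:
    """Per-slice min-max scaling to [0, 1]; a constant slice maps to zeros."""
    arr = np.asarray(image, dtype=np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


# -- augmentation -----------------------------------------------------------

_AUG_KINDS = ("flip", "zoom", "shear", "rotation")


def _transform_pair(image: np.ndarray, mask: np.ndarray, kind: str,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, str]:
    if kind == "flip":
        return image[:, ::-1].copy(), mask[:, ::-1].copy(), "flip"
    if kind == "rotation":
        angle = float(rng.uniform(0.0, 90.0))
        img = rotate(image, angle, order=1, preserve_range=True)
        msk = rotate(mask.astype(np.float32), angle, order=0,
                     preserve_range=True)
        return (img.astype(np.float32), (msk > 0.5).astype(np.uint8),
                f"rotation:{angle:.1f}")
    h, w = image.shape
    centre = np.array([w, h]) / 2.0 - 0.5
    if kind == "zoom":
        factor = float(rng.uniform(0.9, 1.1))
        tf = (AffineTransform(translation=centre)
              + AffineTransform(scale=(1 / factor, 1 / factor))
              + AffineTransform(translation=-centre))
        tag = f"zoom:{factor:.3f}"
    else:  # shear
        shear = float(np.deg2rad(rng.uniform(-10.0, 10.0)))
        tf = (AffineTransform(translation=centre)
              + AffineTransform(shear=shear)
              + AffineTransform(translation=-centre))
        tag = f"shear:{np.rad2deg(shear):.1f}"
    img = warp(image, tf, order=1, preserve_range=True)
    msk = warp(mask.astype(np.float32), tf, order=0, preserve_range=True)
    return img.astype(np.float32), (msk > 0.5).astype(np.uint8), tag


def augment(pairs: list[SlicePair], factor: int = 3,
            seed: int = 0) -> list[SlicePair]:
    """Expand the dataset ``factor``-fold: the originals plus ``factor - 1``
    independently transformed copies of each pair.  The same geometric
    transform (flip / zoom <=10% / shear <=10 deg / rotation in [0, 90] deg)
    is applied to image and mask; masks are re-binarised afterwards."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for _ in range(factor - 1):
        for pair in pairs:
            kind = _AUG_KINDS[rng.integers(len(_AUG_KINDS))]
            img, msk, tag = _transform_pair(pair.image, pair.mask, kind, rng)
            out.append(SlicePair(img, msk, pair.subject_id, pair.slice_index,
                                 augmentation=tag))
    return out


def split(pairs: list, train_fraction: float = 0.8,
          seed: int = 0) -> SplitDataset:
    """Seeded shuffle then partition; |train| = round(train_fraction * N)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train:]]
    return SplitDataset(train=train, validation=val, seed=seed,
                        train_fraction=train_fraction)


# -- end-to-end per subject -------------------------------------------------

def preprocess_subject(image_vol: Volume, mask_vol: Volume,
                       target: int = TARGET_SIZE,
                       fg_threshold: float = 0.02) -> list[SlicePair]:
    """Full pipeline for one subject: slices -> trim -> resize -> normalise."""
    if image_vol.n_slices != mask_vol.n_slices:
        raise ValueError("image and mask volumes have different slice counts")
    slices = extract_slices(image_vol)
    masks = [m.astype(np.uint8) for m in extract_slices(mask_vol)]
    kept_s, kept_m, kept_idx = remove_blank_slices(slices, masks,
                                                   fg_threshold)
    pairs = []
    for img, msk, k in zip(kept_s, kept_m, kept_idx):
        img = normalize(resize_slice(img, target, kind="image"))
        msk = resize_slice(msk, target, kind="mask")
        pairs.append(SlicePair(img, msk, image_vol.subject_id, k))
    return pairs
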