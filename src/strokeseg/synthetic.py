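"""Seeded brain-phantom generator.

Produces single-modality volumes that mimic the gross layout of sub-acute
stroke MRI: an elliptical "brain" with smooth background texture, blank
(all-zero) slices at both ends of the stack, and one or more bright,
Gaussian-blurred lesion blobs with exact binary ground-truth masks.  The
defaults emulate the reference acquisition: 153 slices of 230 x 230 voxels
at 1 mm spacing, trimmed by the preprocessing step to ~61 informative slices
per subject (64 subjects x 61 ~ 3,900 usable images).

Phantoms are deliberately not anatomically realistic; lesions are brighter
than the background by less than the texture + noise spread, so plain
thresholding does not solve the segmentation task.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, zoom as ndi_zoom

from .preprocessing import Volume

__all__ = ["PhantomSpec", "make_phantom", "make_dataset", "make_slice_pairs"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of one phantom volume."""

    n_slices: int = 153
    slice_size: int = 230
    blank_margins: tuple[int, int] = (46, 46)
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (4.0, 20.0)
    lesion_boost: float = 0.4
    background_level: float = 0.3
    texture_amplitude: float = 0.1
    noise_sigma: float = 0.05
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.n_slices < 1 or self.slice_size < 8:
            raise ValueError("volume dimensions too small")
        lo, hi = self.blank_margins
        if lo < 0 or hi < 0 or lo + hi >= self.n_slices:
            raise ValueError("blank margins must leave at least one "
                             "informative slice")
        rlo, rhi = self.lesion_radius_range
        if rlo < 1 or rhi < rlo:
            raise ValueError("lesion radii must satisfy 1 <= lo <= hi")
        if rhi >= 0.35 * self.slice_size:
            raise ValueError("lesion larger than the brain region")
        clo, chi = self.lesion_count_range
        if clo < 0 or chi < clo:
            raise ValueError("invalid lesion count range")


def _brain_mask(size: int) -> np.ndarray:
    """Elliptical brain support, axes ~80% / 90% of the half-size."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    ry, rx = 0.45 * size, 0.40 * size
    return ((yy - cy) ** 2 / ry ** 2 + (xx - cx) ** 2 / rx ** 2) <= 1.0


def _smooth_noise(shape, rng: np.random.Generator, scale: int = 8
                  ) -> np.ndarray:
    """Low-frequency texture: coarse noise upsampled to ``shape``."""
    coarse = rng.standard_normal([max(2, s // scale) for s in shape])
    factors = [s / c for s, c in zip(shape, coarse.shape)]
    smooth = ndi_zoom(coarse, factors, order=1, mode="nearest")
    return smooth[tuple(slice(0, s) for s in shape)]


def make_phantom(spec: PhantomSpec, seed: int = 0,
                 subject_id: str = "sub-000") -> tuple[Volume, Volume]:
    """One (image volume, mask volume) pair, bit-identical per seed."""
    rng = np.random.default_rng(seed)
    d, s = spec.n_slices, spec.slice_size
    lo, hi = spec.blank_margins
    active = np.arange(lo, d - hi)

    brain2d = _brain_mask(s)
    image = np.zeros((d, s, s), dtype=np.float32)
    mask = np.zeros((d, s, s), dtype=np.uint8)

    texture = spec.texture_amplitude * _smooth_noise((len(active), s, s), rng)
    image[active] = (spec.background_level + texture) * brain2d

    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    cy = cx = (s - 1) / 2.0
    ry, rx = 0.45 * s, 0.40 * s
    for _ in range(n_lesions):
        r = rng.uniform(*spec.lesion_radius_range)
        # centre inside the brain ellipse, margin r from its boundary
        for _attempt in range(100):
            ly = rng.uniform(cy - ry + r, cy + ry - r)
            lx = rng.uniform(cx - rx + r, cx + rx - r)
            if ((ly - cy) ** 2 / (ry - r) ** 2
                    + (lx - cx) ** 2 / (rx - r) ** 2) <= 1.0:
                break
        depth = max(1, int(rng.uniform(0.5, 1.5) * r))
        z0 = int(rng.integers(active[0], max(active[0] + 1,
                                             active[-1] - depth + 1)))
        zz = np.arange(z0, min(z0 + depth, active[-1] + 1))
        yy, xx = np.mgrid[0:s, 0:s]
        for z in zz:
            # per-slice radius shrinks toward the lesion's axial ends
            frac = 1.0 - abs((z - z0) - (len(zz) - 1) / 2) / max(len(zz), 1)
            rz = max(1.0, r * (0.6 + 0.4 * frac))
            blob = ((yy - ly) ** 2 + (xx - lx) ** 2) <= rz ** 2
            blob &= brain2d
            mask[z] |= blob.astype(np.uint8)

    soft = gaussian_filter(mask.astype(np.float32), sigma=(0.5, 1.5, 1.5))
    image[active] += spec.lesion_boost * soft[active]
    image[active] += (spec.noise_sigma
                      * rng.standard_normal((len(active), s, s))
                      * brain2d)
    np.clip(image, 0.0, None, out=image)
    # lesions only exist where slices are informative
    mask[:lo] = 0
    if hi:
        mask[d - hi:] = 0

    vol = Volume(subject_id=subject_id, modality="DWI", data=image,
                 spacing=spec.spacing_mm)
    msk = Volume(subject_id=subject_id, modality="mask",
                 data=mask.astype(np.float32), spacing=spec.spacing_mm)
    return vol, msk


def make_dataset(spec: PhantomSpec, n_subjects: int, out_dir,
                 seed: int = 0) -> Path:
    """Write ``n_subjects`` NIfTI volume/mask pairs plus a manifest CSV."""
    from .preprocessing import save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    base = np.random.SeedSequence(seed)
    for i, child in enumerate(base.spawn(n_subjects)):
        sid = f"sub-{i:03d}"
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        vol, msk = make_phantom(spec, seed=sub_seed, subject_id=sid)
        img_path = out / f"{sid}_img.nii.gz"
        msk_path = out / f"{sid}_msk.nii.gz"
        save_volume(vol, img_path)
        save_volume(msk, msk_path)
        rows.append({"subject": sid, "image": img_path.name,
                     "mask": msk_path.name, "n_slices": spec.n_slices,
                     "seed": sub_seed})
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def make_slice_pairs(n_pairs: int, size: int = 64, seed: int = 0,
                     lesion_radius_range: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: ``n_pairs`` independent 2D slice/mask pairs at ``size``.

    Each pair is the centre slice of a small single-lesion phantom; used by
    the smoke-scale training tests and examples.
    """
    if lesion_radius_range is None:
        r = max(2.0, size / 16), max(3.0, size / 6)
    else:
        r = lesion_radius_range
    spec = PhantomSpec(n_slices=3, slice_size=size, blank_margins=(1, 1),
                       lesion_count_range=(1, 2), lesion_radius_range=r)
    images = np.empty((n_pairs, size, size), dtype=np.float32)
    masks = np.empty((n_pairs, size, size), dtype=np.uint8)
    base = np.random.SeedSequence(seed)
    for i, child in enumerate(base.spawn(n_pairs)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        vol, msk = make_phantom(spec, seed=sub_seed)
        img = vol.data[1]
        m = img.max()
        images[i] = img / m if m > 0 else img
        masks[i] = msk.data[1].astype(np.uint8)
    return images, masks
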