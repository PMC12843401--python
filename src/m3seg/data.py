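"""Readers/writers and CT preprocessing.

Supported formats: NIfTI volumes (``.nii``/``.nii.gz``) with spacing taken
from the header, NPZ slice archives (``image``, ``mask``, ``spacing``
arrays), and PNG/JPEG images with PNG label masks. CT volumes arrive in
Hounsfield units and are windowed to the soft-tissue range [-125, 275] HU
before affine normalisation to [0, 1]; photographic inputs bypass the
windowing (their ``is_hu`` flag is False).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentationSample",
    "FormatError",
    "clip_normalize_ct",
    "resize_pair",
    "read_volume",
    "read_image",
    "write_mask",
    "read_mask",
    "save_sample_npz",
    "load_sample_npz",
]

HU_WINDOW = (-125.0, 275.0)


class FormatError(IOError):
    """Unrecognised or corrupt input file."""


@dataclass
class SegmentationSample:
    """An image, its integer label mask, pixel spacing (mm) and provenance."""

    image: np.ndarray            # (H, W) or (H, W, 3) float intensities
    mask: np.ndarray             # (H, W) integer labels
    spacing: tuple = (1.0, 1.0)  # mm per axis (row, col)
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} are not congruent"
            )
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("mask must have an integer dtype")


def clip_normalize_ct(volume: np.ndarray, lo: float = HU_WINDOW[0],
                      hi: float = HU_WINDOW[1]) -> np.ndarray:
    """Window HU values to [lo, hi] and map affinely to [0, 1].

    Monotone non-decreasing: -125 HU -> 0.0, 75 HU -> 0.5, 275 HU -> 1.0,
    everything outside the window saturates.
    """
    if lo >= hi:
        raise ValueError(f"invalid window: lo={lo} >= hi={hi}")
    v = np.asarray(volume, dtype=np.float64)
    return (np.clip(v, lo, hi) - lo) / (hi - lo)


def resize_pair(sample: SegmentationSample, size: int = 224) -> SegmentationSample:
    """Resize image (bilinear) and mask (nearest-neighbour) to size x size.

    Nearest-neighbour keeps the label set of the output a subset of the
    input's; binary masks stay binary.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    from skimage.transform import resize

    h, w = sample.mask.shape
    if (h, w) == (size, size):
        return sample
    out_shape = (size, size) + sample.image.shape[2:]
    image = resize(sample.image.astype(np.float64), out_shape, order=1,
                   mode="edge", anti_aliasing=False, preserve_range=True)
    mask = resize(sample.mask, (size, size), order=0, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(sample.mask.dtype)
    spacing = (sample.spacing[0] * h / size, sample.spacing[1] * w / size)
    return SegmentationSample(image=image, mask=mask, spacing=spacing,
                              source=sample.source, meta=dict(sample.meta))


# ---------------------------------------------------------------------------
# NIfTI / NPZ / PNG
# ---------------------------------------------------------------------------

def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def read_volume(path: str):
    """Read a NIfTI volume or an NPZ slice archive.

    Returns ``(volume, spacing)``; spacing comes from the NIfTI header
    zooms or the archive's ``spacing`` array.
    """
    import nibabel as nib

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        try:
            img = nib.load(path)
            vol = np.asarray(img.get_fdata())
        except Exception as exc:
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        spacing = tuple(float(z) for z in img.header.get_zooms()[: vol.ndim])
        return vol, spacing
    if path.endswith(".npz"):
        try:
            with np.load(path) as archive:
                vol = archive["image"]
                spacing = tuple(float(s) for s in archive["spacing"])
        except Exception as exc:
            raise FormatError(f"cannot read NPZ archive {path}: {exc}") from exc
        return vol, spacing
    raise FormatError(f"unsupported volume format: {path}")


def read_image(path: str) -> np.ndarray:
    """Read a PNG/JPEG image to float intensities in [0, 1]."""
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return arr.astype(np.float64) / 255.0


def write_mask(mask: np.ndarray, path: str):
    """Write an integer label mask as PNG or NIfTI (round-trip exact)."""
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must have an integer dtype")
    if path.endswith(".png"):
        from PIL import Image

        if mask.min() < 0 or mask.max() > 255:
            raise ValueError("PNG masks must have labels in [0, 255]")
        Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
    elif _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.astype(np.int16), affine=np.eye(4)), path)
    else:
        raise FormatError(f"unsupported mask format: {path}")


def read_mask(path: str) -> np.ndarray:
    if path.endswith(".png"):
        from PIL import Image, UnidentifiedImageError

        try:
            with Image.open(path) as im:
                return np.asarray(im.convert("L")).astype(np.int64)
        except (UnidentifiedImageError, OSError) as exc:
            raise FormatError(f"cannot read mask {path}: {exc}") from exc
    if _is_nifti(path):
        import nibabel as nib

        try:
            return np.asarray(nib.load(path).get_fdata()).astype(np.int64)
        except Exception as exc:
            raise FormatError(f"cannot read mask {path}: {exc}") from exc
    raise FormatError(f"unsupported mask format: {path}")


def save_sample_npz(sample: SegmentationSample, path: str):
    np.savez(path, image=sample.image, mask=sample.mask,
             spacing=np.asarray(sample.spacing, dtype=np.float64),
             source=np.array(sample.source))


def load_sample_npz(path: str) -> SegmentationSample:
    try:
        with np.load(path) as archive:
            return SegmentationSample(
                image=archive["image"],
                mask=archive["mask"],
                spacing=tuple(float(s) for s in archive["spacing"]),
                source=str(archive["source"]),
            )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read sample archive {path}: {exc}") from exc
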