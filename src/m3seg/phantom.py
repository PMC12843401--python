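"""Synthetic multi-class phantom generator.

Emulates the structure of abdominal CT slices for exercising the full
pipeline without external data: a noisy background carrying several
"organ" blobs — randomly deformed ellipses — whose areas span from under
1% to over 10% of the canvas (multi-scale), with flat per-class mean
intensities that include at least one low-contrast pair. The mask matches
the blob geometry exactly and every label in ``[0, n_classes)`` is present.
Generation is fully deterministic per seed.
"""

from __future__ import annotations

import csv
import os

import numpy as np

from .data import SegmentationSample, save_sample_npz

__all__ = ["generate_phantom", "generate_dataset"]

# area fractions of the canvas spanned by the organ blobs, largest first
_AREA_RANGE = (0.15, 0.004)
_LOW_CONTRAST_GAP = 0.05  # intensity gap of the deliberately hard class pair


def _blob_mask(size: int, centre, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterise a deformed ellipse: radial Fourier perturbation of a disc."""
    aspect = rng.uniform(0.8, 1.25)
    theta0 = rng.uniform(0, 2 * np.pi)
    n_harm = 4
    amps = rng.normal(0.0, 0.05, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)

    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rows - centre[0], cols - centre[1]
    # rotate into the ellipse frame
    c, s = np.cos(theta0), np.sin(theta0)
    u = c * dr + s * dc
    v = -s * dr + c * dc
    rho = np.hypot(u / aspect, v * aspect)
    ang = np.arctan2(v, u)
    wobble = np.ones_like(ang)
    for h, (a, p) in enumerate(zip(amps, phases), start=2):
        wobble += a * np.cos(h * ang + p)
    return rho <= radius * np.clip(wobble, 0.5, 1.5)


def _intensities(n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Per-class mean intensities: background dark, foregrounds spread over
    [0.3, 0.9] with classes 1 and 2 forming a low-contrast pair."""
    levels = np.empty(n_classes)
    levels[0] = 0.15
    fg = np.linspace(0.35, 0.9, max(1, n_classes - 1))
    levels[1:] = rng.permutation(fg)
    if n_classes >= 3:
        levels[2] = levels[1] + _LOW_CONTRAST_GAP * np.sign(0.6 - levels[1])
    return levels


def generate_phantom(seed: int, size: int = 224, n_classes: int = 9,
                     noise_sigma: float = 0.03) -> SegmentationSample:
    """Generate one phantom slice.

    Blob areas are log-spaced from 15% down to 0.4% of the canvas (largest
    drawn first so small structures are never buried), guaranteeing both a
    large and a sub-1% structure whenever there are >= 3 organ classes.
    With ``noise_sigma=0`` the pixel values inside each blob equal the
    class's assigned mean exactly.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if size < 32:
        raise ValueError("size must be >= 32")
    n_blobs = n_classes - 1
    max_radius = size * np.sqrt(_AREA_RANGE[0] / np.pi)
    if 2.5 * max_radius / np.sqrt(n_blobs) < 2.0:
        raise ValueError(f"canvas of size {size} is too small for {n_classes} classes")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A17]))
    fracs = np.geomspace(_AREA_RANGE[0], _AREA_RANGE[1], n_blobs)
    levels = _intensities(n_classes, rng)

    mask = np.zeros((size, size), dtype=np.int64)
    for label, frac in zip(range(1, n_classes), fracs):
        radius = size * np.sqrt(frac / np.pi)
        for _ in range(200):  # re-place until the label survives overwrites
            margin = min(radius * 1.3 + 1, size / 2 - 1)
            centre = rng.uniform(margin, size - margin, 2)
            blob = _blob_mask(size, centre, radius, rng)
            if not blob.any():
                continue
            # limit overlap with already-placed organs so earlier (larger)
            # blobs keep (most of) their area
            if (mask[blob] != 0).mean() > 0.15:
                continue
            candidate = mask.copy()
            candidate[blob] = label
            if all((candidate == l).any() for l in range(label + 1)):
                mask = candidate
                break
        else:
            raise RuntimeError(f"could not place blob for label {label}")

    image = levels[mask]
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, 1.0)
    return SegmentationSample(
        image=image.astype(np.float64), mask=mask, spacing=(1.0, 1.0),
        source=f"phantom-seed{seed}",
        meta={"levels": levels, "n_classes": n_classes, "seed": int(seed)},
    )


def generate_dataset(n: int, seed: int, out_dir: str, size: int = 224,
                     n_classes: int = 9) -> list[dict]:
    """Write ``n`` phantom samples as NPZ files plus a CSV manifest.

    Returns the manifest rows. Regeneration with the same arguments
    reproduces byte-identical arrays (child seeds are derived
    deterministically from ``seed``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n):
        child_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31))
        sample = generate_phantom(child_seed, size=size, n_classes=n_classes)
        sample_id = f"phantom_{i:04d}"
        path = os.path.join(out_dir, f"{sample_id}.npz")
        save_sample_npz(sample, path)
        rows.append({"id": sample_id, "seed": child_seed, "n_classes": n_classes,
                     "size": size, "path": path})
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "seed", "n_classes", "size", "path"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
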